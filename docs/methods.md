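# Methods

## Scope and model

`csfhydro` models pulsatile cerebrospinal fluid (CSF) flow in the
cervical spinal subarachnoid space (SSS) as laminar, incompressible,
Newtonian and *fully developed*: at each of nine axial stations
(FM, C1, C2M, C2P, C3–C7) the axial velocity field solves, per cardiac
harmonic `n`, the unsteady-Stokes (complex Helmholtz) problem

    (i n ω₀ / ν) û_n − ∇² û_n = G_n / μ,    û_n = 0 on every wall,

on the station's multiply-connected cross-section, with the complex
pressure-gradient amplitude `G_n` fixed by matching the sectional flux to
the waveform harmonic `Q_n`.  This is the Womersley pipe/annulus solution
generalized to arbitrary obstructed sections.  Its assumptions:

* **Linearity** — convective acceleration is dropped.  The internal-flow
  Reynolds numbers of the default configuration (mean ≈ 168 without
  obstructions) and Womersley numbers (α ≈ 10–30) put the flow in the
  laminar, inertia-dominated oscillatory regime where the linear model is
  a standard and well-characterized approximation.
* **Full development** — no axial variation within a segment.  Segment
  pressure drops use a piecewise-uniform approximation (below); genuinely
  3D features (secondary flow, vortex shedding, jets) are *not* produced
  by this solver and enter the pipeline only through imported or
  synthetic velocity fields.
* **Rigid walls, zero outlet pressure** — only pressure *gradients* are
  meaningful, never absolute pressures.

The solver is exactly periodic, so "cycle three" of a simulation equals
cycle one by construction; the cycle-independence study therefore reports
zero (to round-off) as its analytic expectation.

## Geometry

Dura and cord are circles with a configurable eccentric offset; sections
are shapely polygons, so area `A_c`, wetted perimeter `P` (dura + cord +
obstruction boundaries) and `D_h = 4A_c/P` are exact polygon quantities
at 512 boundary points per circle (0.1 % of the analytic values).

Nerve roots are stadium footprints of width equal to the measured root
thickness, extending radially from the cord with in-plane extent
`min(RL·cos θ, gap)`; the per-level radicular lengths `RL`, descending
angles `θ` and thicknesses ship as a CSV of cadaveric measurements
(8 levels × 2 sides × dorsal/ventral).  Denticulate ligaments are thin
lateral rectangles (default 0.12 mm within the allowed 0.1–0.15 mm band)
spanning cord to dura midway between the root pairs.  Station plane `L`
carries the structures of level `L` (both C2 planes share the C2 roots);
the foramen-magnum plane is always clear, the first roots appearing at C1.

Where roots and ligaments span the whole dura–cord gap the section is
genuinely partitioned into several channels.  This is anatomical, not a
meshing defect: the solver treats the channels as parallel conduits
sharing one axial pressure gradient, which is exact for fully developed
flow.

Default station radii: cord radii taper over literature-typical cervical
values (4.6 → 3.9 mm); dura radii are set so the *unobstructed* annulus
areas reproduce published adult cervical SSS areas station by station
(610 mm² at FM down to ≈ 150 mm² at C5).  These are inputs taken from
printed tables, not fitted quantities.  Dorsal-root rootlet ridges are
recorded as metadata on 2D sections (they are below section resolution)
and applied only as a sinusoidal surface perturbation in the 3D STL
export.  Axial station spacing defaults to 17.5 mm (140 mm cervical
span), configurable; inter-station distances are not published, so equal
spacing is the neutral choice.

## Synthetic inputs

The in-vivo inputs of subject-specific studies (MRI flow waveforms, 4D
velocity fields) are not distributable, so the generator provides:

* **Waveform** — zero-net-flux harmonic sum; default: dominant
  fundamental plus a 25 %-amplitude second harmonic phased so the caudal
  (systolic) peak is sharper than the diastolic one; period 1 s.  The
  caudal stroke volume default (0.65 mL) is calibrated so the plain
  geometry's internal Reynolds numbers land in the published adult range
  (mean ≈ 170, max ≈ 190) — i.e., the waveform amplitude is inferred from
  printed study conditions, the only ones available.  CSF bulk production
  (~0.35 mL/min) is negligible per cycle and excluded.
* **Fields** — annular-mask grids with prescribed axial profiles (plug,
  annular-Poiseuille), Rankine vortices, a localized shedding tone and
  seeded Gaussian noise.  Ground truth (SFP series, wall shear, extrema,
  dominant frequency) is computed from the closed-form definitions on a
  4× refined grid, independent of the sampled arrays and noise-free.

What the generator does **not** emulate: MRI noise physics and velocity
encoding, anterior-dominant velocity asymmetry, genuine 3D vortex
dynamics, wall motion.  Passing recovery tests therefore demonstrates
correctness of the *metrics*, not fidelity of any particular subject's
flow.

## Numerics

* **Meshing** — Delaunay triangulation of a graded point cloud: boundary
  rings at `h_wall`, offset layers whose spacing grows geometrically
  (factor `growth`) to `h_core`, then a hexagonal core lattice; triangles
  with centroids outside the polygon are discarded.  The grading exists
  to resolve the oscillatory (Stokes) boundary layer, δ = √(ν/ω) ≈
  0.33 mm at 1 Hz.  Defaults for single-section solves
  (`h_wall = 0.025 mm, h_core = 0.1 mm, growth = 1.12`) give relative L2
  errors < 10⁻³ against the Bessel closed forms; whole-geometry runs use
  the coarser named levels (coarse/medium/fine) because their outputs
  (directional deltas, impedance) are far less resolution-sensitive.
* **Flux matching** — by linearity one unit-forcing solve per harmonic;
  the sectional flux then equals `Q(t)` at every time step to machine
  precision (asserted, not approximated).
* **Segment pressure drops** — each segment uses the solve of its
  *cranial* bounding station times the segment length.  With first roots
  at C1, the FM–C1 segment then depends only on the clear FM plane, which
  reproduces the finding that fine structures leave the FM–C1 pressure
  gradient essentially unchanged; all caudal segments use obstructed
  planes.
* **Wall shear stress** — one-sided second-order differences of
  tangential velocity at distances d and 2d along the inward normal
  (`v'(0) ≈ (4v(d) − v(2d))/2d`, exact for quadratic profiles), with
  d from the near-wall mesh spacing (solver fields) or grid spacing
  (synthetic fields); at least two interior sample layers are required.
* **Impedance** — DFT over exactly one cycle; harmonics of the cardiac
  fundamental with `f_n ≤ 8 Hz`; harmonics with `|Q_n|` below 10⁻⁸ of the
  maximum are excluded (and counted) to avoid dividing by vanishing flow
  coefficients.  "Harmonics 1–8 Hz" is read as frequency-capped harmonic
  indices; at T = 1 s the two readings coincide.
* **Bidirectional velocity** — `B(t) = v_max(t) − v_min(t)` only when the
  spatial extrema have opposite signs, else 0; duration counts time steps
  with `B` above 1 mm/s per plane.  Requiring strictly opposite signs
  makes unidirectional flow read 0, treating bidirectionality as a
  distinct flow feature.  The threshold is applied per plane.
* **Secondary flow parameter** — speed-weighted non-streamwise fraction,
  bounded in [0, 1]; identically 0 for solver-produced (axial-only)
  fields, by construction.
* **Vortex-shedding frequency** — largest-magnitude FFT peak of the
  detrended probe series (≥ 2 cycles required); optional removal of the
  cardiac-harmonic reconstruction isolates non-cardiac tones; a flat
  spectrum is flagged rather than silently reported as 0 Hz.
* **Independence studies** — relative error
  `e = 100·max|p_c − p_f| / range(p_f)` over pressure samples along three
  200-point axial paths at peak systole (the paths are identical in a
  fully developed model; all three are emitted to keep the layout
  conventional).  The error norm is L∞ normalized by the fine-solution
  range; the time-step ladder compares linear reconstructions of each
  sampling (T/50, T/100, T/200) on a dense reference grid, since the
  harmonic sum itself has no truncation error at sample points.  Gates:
  3 % (mesh), 2 % (time step), 1.5 % (cycles).

## Tunable parameters

| parameter | default | units | note |
|---|---|---|---|
| density ρ | 993 | kg/m³ | water at 37 °C |
| viscosity μ | 6.97·10⁻⁴ | Pa·s | ν = μ/ρ ≈ 7.02·10⁻⁷ m²/s |
| period T | 1.0 | s | cardiac cycle |
| stroke volume | 0.65 | mL | caudal phase; see above |
| time steps / cycle | 100 | – | T/100; 50/200 for the ladder |
| ligament thickness | 0.12 | mm | allowed 0.1–0.15 |
| NRDL scale | 1.0 | – | 0.70–0.85 for pediatric-sized models |
| h_wall / h_core | 0.025 / 0.1 | mm | single-section default mesh |
| bidirectional threshold | 1.0 | mm/s | per plane |
| impedance cap f_max | 8 | Hz | cardiac harmonics |

## Known limitations

The surrogate cannot produce secondary flow, jets between roots, or
vortex shedding — quantities that depend on them (nonzero SFP, shedding
tones) are only meaningful on imported or synthetic 3D fields.  Station
sections change abruptly between planes (piecewise-uniform); entrance and
transition losses are absent, so absolute pressure-gradient magnitudes
are lower bounds relative to a full 3D solve, while the with/without
comparisons (the package's purpose) are differences under identical
assumptions.  Eccentricity defaults to zero; the published sections are
eccentric and lobed, which shifts `P` and `D_h` somewhat at equal area.
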
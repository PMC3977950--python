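# csfhydro

Cerebrospinal fluid (CSF) pulses up and down the spinal subarachnoid
space (SSS) — the annular, CSF-filled gap between the spinal cord and the
dura — once per heartbeat.  Fine intradural structures, the spinal nerve
roots and denticulate ligaments (NRDL), partially obstruct this annulus,
and their effect on CSF velocities, mixing, wall shear stress and the
resistance to pulsatile flow matters for understanding craniospinal
disorders (Chiari malformation, syringomyelia) and intrathecal drug
delivery.  `csfhydro` is a desk-scale pipeline for exactly this question:
it builds parametric cervical SSS cross-sections with idealized NRDL from
cadaveric measurements, solves linearized oscillatory flow on them per
cardiac harmonic, and evaluates the standard CSF hydrodynamic parameter
suite with and without the fine structures.

It is aimed at researchers in CSF biofluid dynamics who want a fast,
fully testable analog of a 3D subject-specific CFD study: every input the
full studies leave unpublished (MRI flow waveforms, velocity fields) is
replaced by a synthetic generator with known ground truth.

## The model

**Geometry.**  Nine axial stations (FM, C1, C2M, C2P, C3–C7) are eccentric
annuli (dura radius `R_d`, cord radius `R_c`); nerve roots enter a plane
as stadium footprints of width equal to the root thickness `t` and
in-plane extent `min(RL·cosθ, gap)` — `RL` the radicular line length and
`θ` the descending angle from a per-level measurement table — and
denticulate ligaments as thin lateral membranes (0.1–0.15 mm) spanning
cord to dura.  Each section carries its area `A_c`, wetted perimeter `P`
and hydraulic diameter `D_h = 4·A_c/P`.

**Flow.**  CSF is water-like at 37 °C (ρ = 993 kg/m³, μ = 6.97·10⁻⁴ Pa·s)
and the flow laminar.  For each cardiac harmonic `n` of the volumetric
waveform `Q(t)` the complex axial velocity amplitude solves the
unsteady-Stokes (Womersley-type) problem on the cross-section

    (i·n·ω₀/ν)·û_n − ∇²û_n = G_n/μ,   û_n = 0 on all walls,

with the axial pressure gradient `G_n` fixed by flux matching
`∫ û_n dA = Q_n`.  This is solved with P1 finite elements on
boundary-layer-graded triangulations; `ω = 0` reduces to Poiseuille flow.

**Metrics.**  Peak systolic/diastolic velocity, bidirectional velocity
(magnitude and >1 mm/s duration), internal and external Reynolds numbers,
secondary flow parameter `SFP = ∫|v_inplane| dV / ∫|v| dV`, wall shear
stress `τ_w = μ·‖∂v_t/∂n‖` by one-sided second-order wall-normal
differences, per-segment peak pressure gradient, vortex-shedding
frequency, and integrated longitudinal impedance
`Z_L = Σ_{f_n ≤ 8 Hz} |ΔP_n|/|Q_n|` (reported in dyn·s/cm⁵).

## Worked example

```python
import csfhydro as ch

wf = ch.make_flow_waveform()                   # 0.65 mL caudal stroke, T = 1 s
geo_w  = ch.build_geometry(with_nrdl=True)
geo_wo = ch.build_geometry(with_nrdl=False)

print(geo_w.metrics_table()[["station", "A_c_mm2", "D_h_mm"]].head(3))
#   station     A_c_mm2     D_h_mm
# 0      FM  609.976036  20.147621
# 1      C1  303.238004   7.357772
# 2     C2M  210.969788   5.842243

sols = ch.solve_geometry(geo_w, ch.CSF, wf)
traces = ch.segment_pressure_traces(sols, geo_w)
ili = ch.ili_pipeline(geo_w, wf, ch.CSF, solutions=sols)
print(ili.head(3).to_string(index=False))
# segment  Z_L_dyne_cm5  n_harmonics  n_excluded
#   FM-C1      5.578363            2           6
#  C1-C2M     11.979569            2           6
# C2M-C2P     17.690723            2           6
```

(The default waveform carries two cardiac harmonics, so six of the eight
sub-8 Hz harmonics carry no flow and are excluded from the sum.)

At C1 the nerve roots shrink the sectional area from 333 mm² to
303 mm² and the hydraulic diameter from 13.5 mm to 7.4 mm; the impedance
per segment rises correspondingly — adding the NRDL raises `Z_L` in every
obstructed segment while the unobstructed FM–C1 segment is untouched.
The same comparison from the shell:

```bash
csfhydro run --out runs/with --with-nrdl
csfhydro run --out runs/without --no-with-nrdl
csfhydro compare runs/with runs/without
csfhydro independence mesh
```

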
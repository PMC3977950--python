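"""Hydrodynamic parameter suite for CSF velocity fields.

All metrics operate on :class:`~csfhydro.fieldio.VelocityField` objects
(solver-produced, synthetic, or imported) and/or on flow waveforms and
cross-sections:

* peak systolic / diastolic velocity (max speed at peak caudal / cranial
  flux);
* bidirectional velocity magnitude and above-threshold duration;
* internal (hydraulic-diameter) and external (structure-length) Reynolds
  numbers;
* secondary flow parameter, the speed-weighted non-streamwise fraction;
* peak wall shear stress from one-sided second-order wall-normal
  differences of tangential velocity;
* pressure-gradient statistics and vortex-shedding frequency detection.

Sign convention: axial = y, positive cranial; systole is the phase of peak
caudal (negative) flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

from .anatomy import CrossSection, GeometryModel
from .fieldio import VelocityField
from .fluid import FluidProperties
from .synthetic import FlowWaveform

#: Bidirectional-flow detection threshold, cm/s (= 1.0 mm/s).
BIDIRECTIONAL_THRESHOLD = 0.1


class MetricError(ValueError):
    pass


def plane_slice(field: VelocityField, y: float | None = None,
                tol: float = 1e-6) -> np.ndarray:
    """Indices of field nodes on the axial plane at y (all nodes if None)."""
    if y is None:
        return np.arange(len(field.points))
    idx = np.where(np.abs(field.points[:, 1] - y) <= tol)[0]
    if len(idx) == 0:
        raise MetricError(f"plane y={y} lies outside the field domain")
    return idx


def _systole_diastole_steps(field: VelocityField,
                            waveform: FlowWaveform | None) -> tuple[int, int]:
    """Time indices of peak caudal and peak cranial flux.

    Peak systole/diastole are global (flux-waveform) times, not per-plane.
    """
    if waveform is not None:
        q = waveform.evaluate(field.times)
    else:
        q = field.flux()
    return int(np.argmin(q)), int(np.argmax(q))


def peak_velocities(field: VelocityField, y: float | None = None,
                    waveform: FlowWaveform | None = None) -> tuple[float, float]:
    """(V_sys, V_dia): max speed in the plane at peak caudal/cranial flux, cm/s."""
    idx = plane_slice(field, y)
    k_sys, k_dia = _systole_diastole_steps(field, waveform)
    speed = field.speed[:, idx]
    return float(speed[k_sys].max()), float(speed[k_dia].max())


def bidirectional_velocity(
    field: VelocityField, y: float | None = None,
    threshold: float = BIDIRECTIONAL_THRESHOLD,
) -> tuple[float, float]:
    """Bidirectional velocity magnitude (cm/s) and duration (s) in a plane.

    B(t) = v_max(t) - v_min(t) where v_max/v_min are the spatial extrema of
    the signed axial velocity, counted only when flow is simultaneously
    caudal somewhere and cranial elsewhere (v_max > 0 > v_min); duration is
    the within-cycle time for which B exceeds the threshold (1 mm/s).
    """
    idx = plane_slice(field, y)
    v = field.axial_velocity[:, idx]
    vmax = v.max(axis=1)
    vmin = v.min(axis=1)
    b = np.where((vmax > 0) & (vmin < 0), vmax - vmin, 0.0)
    n_cycle = len(field.times)
    if field.period and field.dt:
        per_cycle = int(round(field.period / field.dt))
        n_cycle = min(per_cycle, len(field.times))
    duration = float(np.count_nonzero(b[:n_cycle] > threshold) * field.dt)
    return float(b.max()), duration


def reynolds_internal(waveform: FlowWaveform, section: CrossSection,
                      fluid: FluidProperties) -> float:
    """Re = V_mean_max * D_h / nu with V_mean_max = max_t |Q(t)| / A_c."""
    a_m2 = section.area * 1e-6
    if a_m2 <= 0:
        raise MetricError("section area must be positive")
    v_mean_max = np.max(np.abs(waveform.samples)) * 1e-6 / a_m2   # m/s
    dh_m = section.hydraulic_diameter * 1e-3
    return float(v_mean_max * dh_m / fluid.kinematic_viscosity)


@dataclass(frozen=True)
class ExternalFlowSpec:
    """External-flow Reynolds specification for one obstructing structure."""

    structure: str               # e.g. "C5 left dorsal root"
    length: float                # characteristic length L, mm (flat surface
                                 # midway between cord and dura)
    probe: tuple[float, float, float]  # upstream probe location, mm

    def __post_init__(self):
        if self.length <= 0:
            raise MetricError("characteristic length must be positive")


def reynolds_external(field: VelocityField, spec: ExternalFlowSpec,
                      fluid: FluidProperties,
                      waveform: FlowWaveform | None = None) -> float:
    """Re_L = U_inf * L / nu; U_inf sampled at the probe at peak systole."""
    d = np.linalg.norm(field.points - np.asarray(spec.probe), axis=1)
    nearest = int(np.argmin(d))
    if d[nearest] > 5.0:
        raise MetricError(
            f"probe {spec.probe} lies outside the field domain "
            f"(nearest node {d[nearest]:.1f} mm away)")
    k_sys, _ = _systole_diastole_steps(field, waveform)
    u_inf = field.speed[k_sys, nearest] * 1e-2       # cm/s -> m/s
    return float(u_inf * spec.length * 1e-3 / fluid.kinematic_viscosity)


def secondary_flow_parameter(
    field: VelocityField, y_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, float]:
    """SFP(t) and its cycle peak over a volume between two axial planes.

    SFP(t) = int |v_inplane| dV / int |v| dV, the speed fraction carried by
    non-streamwise components; 0 when the field is axial-only and defined
    as 0 when the total speed integral vanishes.
    """
    if y_range is None:
        idx = np.arange(len(field.points))
    else:
        lo, hi = sorted(y_range)
        idx = np.where((field.points[:, 1] >= lo - 1e-9)
                       & (field.points[:, 1] <= hi + 1e-9))[0]
    if len(idx) == 0:
        raise MetricError("empty integration volume")
    w = field.weights[idx]
    num = field.inplane_speed[:, idx] @ w
    den = field.speed[:, idx] @ w
    sfp = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return sfp, float(sfp.max())


def one_sided_wall_gradient(v_d: np.ndarray, v_2d: np.ndarray,
                            d: float) -> np.ndarray:
    """Second-order one-sided wall-normal derivative with v(0) = 0 (no slip).

    v'(0) ~= (4 v(d) - v(2d)) / (2 d); exact for quadratic profiles.
    """
    return (4.0 * np.asarray(v_d) - np.asarray(v_2d)) / (2.0 * d)


def wall_shear_from_samples(vt_d, vt_2d, d_mm: float,
                            fluid: FluidProperties) -> np.ndarray:
    """Wall shear stress (Pa) from tangential-velocity samples (cm/s) at
    distances d and 2d (mm) along the inward wall normal."""
    grad = one_sided_wall_gradient(np.asarray(vt_d), np.asarray(vt_2d), d_mm)
    # cm/s per mm = 10 1/s
    return fluid.dynamic_viscosity * np.abs(grad) * 10.0


def wall_shear_stress_annulus(field: VelocityField, fluid: FluidProperties,
                              n_wall: int = 180,
                              probe_distance: float | None = None) -> float:
    """Peak wall shear stress (Pa) of an annular field over walls and cycle.

    Samples all three velocity components at one and two probe distances
    along the inward radial normal of both walls, removes the wall-normal
    component, and applies the one-sided second-order difference.  Needs
    at least two interior sample layers between probe rings and the
    opposite wall.
    """
    ri = field.attrs.get("r_inner")
    ro = field.attrs.get("r_outer")
    if ri is None or ro is None:
        raise MetricError("field lacks annulus wall metadata (r_inner/r_outer)")
    d = probe_distance if probe_distance is not None else field.attrs.get("spacing")
    if d is None:
        raise MetricError("probe distance unknown: no grid spacing metadata")
    gap = ro - ri
    if gap <= 0 or 2.0 * d >= gap:
        raise MetricError("fewer than 2 interior sample layers inside the gap")

    theta = np.linspace(0.0, 2.0 * math.pi, n_wall, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    probes = []
    normals = []
    for r_wall, sign in ((ro, -1.0), (ri, +1.0)):
        if r_wall == 0:
            continue
        for mult in (1.0, 2.0):
            rr = r_wall + sign * mult * d
            probes.append(np.column_stack([rr * ct, rr * st]))
        normals.append(np.column_stack([sign * ct, sign * st]))
    probes = np.concatenate(probes)  # (walls*2*n_wall, 2) ordered d,2d per wall

    xy = field.points[:, [0, 2]]
    K, N = len(field.times), len(field.points)
    # one multivalued interpolation: (N, K*3) values, evaluated at all probes
    values = field.velocity.transpose(1, 0, 2).reshape(N, K * 3)
    interp = LinearNDInterpolator(xy, values, fill_value=0.0)
    sampled = interp(probes).reshape(len(probes), K, 3)
    tau_peak = 0.0
    n_sets = len(probes) // (2 * n_wall)
    for k in range(K):
        vel = sampled[:, k, :]                   # (n_probes, 3) cm/s
        for w in range(n_sets):
            v_d = vel[(2 * w) * n_wall:(2 * w + 1) * n_wall]
            v_2d = vel[(2 * w + 1) * n_wall:(2 * w + 2) * n_wall]
            nrm = normals[w]
            n3 = np.column_stack([nrm[:, 0], np.zeros(n_wall), nrm[:, 1]])
            vt_d = v_d - (np.sum(v_d * n3, axis=1, keepdims=True)) * n3
            vt_2d = v_2d - (np.sum(v_2d * n3, axis=1, keepdims=True)) * n3
            grad = one_sided_wall_gradient(vt_d, vt_2d, d)
            tau = fluid.dynamic_viscosity * np.linalg.norm(grad, axis=1) * 10.0
            tau_peak = max(tau_peak, float(tau.max()))
    return tau_peak


def wall_shear_stress_solution(solution, times: np.ndarray) -> float:
    """Peak wall shear stress (Pa) of a per-harmonic section solution.

    Uses the mesh's inward boundary normals; tangential velocity is the
    axial component (the solver field has no in-plane flow).  The probe
    distance per wall node is its distance to the nearest interior node.
    """
    from matplotlib.tri import LinearTriInterpolator, Triangulation
    from scipy.spatial import cKDTree

    mesh = solution.mesh
    bidx = np.where(mesh.boundary)[0]
    interior = mesh.points[~mesh.boundary]
    d = cKDTree(interior).query(mesh.points[bidx])[0]        # mm, per node
    d = np.maximum(d, 1e-6)
    p_d = mesh.points[bidx] + mesh.boundary_normals[bidx] * d[:, None]
    p_2d = mesh.points[bidx] + mesh.boundary_normals[bidx] * (2.0 * d)[:, None]

    tri = Triangulation(mesh.points[:, 0], mesh.points[:, 1], mesh.triangles)
    grad_t = np.zeros((len(times), len(bidx)), dtype=complex)
    for h in solution.harmonics:
        for part, op in ((h.u.real, 1.0), (h.u.imag, 1.0j)):
            f = LinearTriInterpolator(tri, part)
            v_d = np.asarray(f(p_d[:, 0], p_d[:, 1]).filled(0.0))
            v_2d = np.asarray(f(p_2d[:, 0], p_2d[:, 1]).filled(0.0))
            g = (4.0 * v_d - v_2d) / (2.0 * d)               # (m/s)/mm
            grad_t += op * np.exp(1j * h.omega * times)[:, None] * g[None, :]
    # (m/s)/mm = 1e3 1/s
    tau = solution.fluid.dynamic_viscosity * np.abs(np.real(grad_t)) * 1e3
    return float(tau.max())


def pressure_gradient_stats(segment_traces: pd.DataFrame) -> pd.DataFrame:
    """Peak |dP| per segment from per-segment pressure-drop traces (Pa).

    The whole-model FM-C7 trace is the telescoping sum of segment traces.
    """
    cols = [c for c in segment_traces.columns if c != "t_s"]
    rows = [dict(segment=c, dP_peak_Pa=float(np.abs(segment_traces[c]).max()))
            for c in cols]
    return pd.DataFrame(rows)


@dataclass
class FrequencyResult:
    frequency_hz: float
    flat_spectrum: bool
    cardiac_frequency_hz: float


def vortex_frequency(series: np.ndarray, period: float, dt: float,
                     non_cardiac: bool = False) -> FrequencyResult:
    """Dominant fluctuation frequency of a velocity probe series.

    The series must span at least two flow cycles at uniform sampling; the
    mean is removed and the largest-magnitude FFT peak is reported.  With
    ``non_cardiac=True`` the best-fit reconstruction from harmonics of the
    cardiac fundamental 1/T is subtracted first, isolating shedding tones
    that are not locked to the heart rate.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n * dt < 2.0 * period - 1e-9:
        raise MetricError("series must span at least two flow cycles")
    x = series - series.mean()
    f0 = 1.0 / period
    freqs = np.fft.rfftfreq(n, dt)
    spec = np.fft.rfft(x)
    if non_cardiac:
        df = freqs[1] if len(freqs) > 1 else 0.0
        cardiac = np.isclose(freqs % f0, 0.0, atol=0.51 * df) \
            | np.isclose(freqs % f0, f0, atol=0.51 * df)
        spec = np.where(cardiac, 0.0, spec)
    mag = np.abs(spec)
    mag[0] = 0.0
    if mag.max() <= 1e-12 * max(np.abs(x).max(), 1e-300) or mag.max() == 0.0:
        return FrequencyResult(0.0, True, f0)
    return FrequencyResult(float(freqs[np.argmax(mag)]), False, f0)


# ---------------------------------------------------------------------------
# Pipeline tables


def plane_metrics_table(solutions: dict, waveform: FlowWaveform,
                        fluid: FluidProperties,
                        n_steps: int = 100) -> pd.DataFrame:
    """Per-station metrics table (Table-3/4 left block layout)."""
    rows = []
    for st, sol in solutions.items():
        sec = sol.section
        fld = sol.time_domain(n_steps=n_steps)
        v_sys, v_dia = peak_velocities(fld, waveform=waveform)
        v_bi, bi_dur = bidirectional_velocity(fld)
        rows.append(dict(
            station=st,
            D_h_mm=sec.hydraulic_diameter,
            A_c_mm2=sec.area,
            V_sys_cm_s=v_sys,
            V_dia_cm_s=v_dia,
            V_bi_cm_s=v_bi,
            bi_duration_s=bi_dur,
            Re_internal=reynolds_internal(waveform, sec, fluid),
        ))
    return pd.DataFrame(rows)


def segment_metrics_table(solutions: dict, geometry: GeometryModel,
                          segment_traces: pd.DataFrame,
                          n_steps: int = 100) -> pd.DataFrame:
    """Per-segment metrics (SFP, peak WSS, peak pressure drop).

    The solver surrogate is axial-only, so its SFP is identically zero;
    nonzero SFP requires imported or synthetic 3D fields.
    """
    times = segment_traces["t_s"].to_numpy()
    rows = []
    for seg in geometry.segments:
        up, dn = seg
        name = f"{up}-{dn}"
        tau = wall_shear_stress_solution(solutions[up], times)
        sfp_series, sfp_peak = secondary_flow_parameter(
            solutions[up].time_domain(n_steps=n_steps))
        rows.append(dict(
            segment=name,
            SFP_peak=sfp_peak,
            tau_w_peak_Pa=tau,
            dP_peak_Pa=float(np.abs(segment_traces[name]).max()),
        ))
    return pd.DataFrame(rows)
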
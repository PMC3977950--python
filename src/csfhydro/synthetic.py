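"""Synthetic study inputs: cardiac-gated flow waveforms and 3D fields.

The in-vivo inputs of a subject-specific CSF study (phase-contrast MRI
flow waveforms, time-resolved velocity fields) are not distributable, so
this module generates physically plausible stand-ins with *known*
ground-truth values for every downstream metric:

* a periodic, zero-net-flux volumetric flow waveform with cardiac-harmonic
  content, systolic (caudal) peak sharper than the diastolic one;
* velocity fields on an annular mask with prescribed axial jets, in-plane
  (Rankine) vortices, an optional vortex-shedding tone, and seeded
  Gaussian noise.

CSF oscillates: net bulk production per cardiac cycle is negligible and
excluded, so the default waveform integrates to zero over a cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fieldio import VelocityField
from .fluid import DEFAULT_VISCOSITY

DEFAULT_PERIOD = 1.0          # s, heart-rate ~60 bpm
#: mL per caudal phase; with the default geometry this places the internal
#: Reynolds numbers in the laminar range (mean ~170, max ~190) measured for
#: adult cervical CSF flow.
DEFAULT_STROKE_VOLUME = 0.65
#: (harmonic n, relative amplitude, phase rad): dominant fundamental with a
#: 25%-amplitude second harmonic phased to sharpen the caudal (systolic) peak.
DEFAULT_HARMONICS = ((1, -1.0, 0.0), (2, 0.25, math.pi / 2))


class SyntheticError(ValueError):
    pass


@dataclass
class FlowWaveform:
    """Periodic volumetric flow Q(t), mL/s, sampled at t_k = k T / N."""

    period: float
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.period <= 0:
            raise SyntheticError("period must be positive")
        if len(self.samples) < 16:
            raise SyntheticError(
                "need at least 16 samples per cycle to resolve the "
                "cardiac-harmonic content")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.period / self.n_samples

    @property
    def omega0(self) -> float:
        return 2.0 * math.pi / self.period

    def coefficients(self) -> np.ndarray:
        """One-sided complex harmonics Q_n with Q(t) = Re sum Q_n e^{i n w0 t}."""
        c = np.fft.rfft(self.samples) / self.n_samples
        q = 2.0 * c
        q[0] = c[0]
        if self.n_samples % 2 == 0:
            q[-1] = c[-1]
        return q

    def evaluate(self, t) -> np.ndarray:
        """Band-limited evaluation at arbitrary times via the harmonic sum."""
        q = self.coefficients()
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for n, qn in enumerate(q):
            out = out + np.real(qn * np.exp(1j * n * self.omega0 * t))
        return out

    def net_flux(self) -> float:
        """Volume transported per cycle, mL (zero for pure oscillation)."""
        return float(np.mean(self.samples) * self.period)

    def stroke_volume(self) -> float:
        """Magnitude of volume carried during the caudal (Q < 0) phase, mL."""
        dt = self.period / self.n_samples
        return float(-np.sum(self.samples[self.samples < 0.0]) * dt)

    @property
    def systole_fraction(self) -> float:
        return float(np.mean(self.samples < 0.0))

    @property
    def peak_caudal(self) -> float:
        return float(-np.min(self.samples))

    @property
    def peak_cranial(self) -> float:
        return float(np.max(self.samples))

    def t_peak_systole(self) -> float:
        return float(self.times[np.argmin(self.samples)])

    def t_peak_diastole(self) -> float:
        return float(self.times[np.argmax(self.samples)])

    def resampled(self, n_samples: int) -> "FlowWaveform":
        return FlowWaveform(self.period, self.evaluate(
            np.arange(n_samples) * self.period / n_samples))


def make_flow_waveform(
    period: float = DEFAULT_PERIOD,
    stroke_volume: float | None = DEFAULT_STROKE_VOLUME,
    harmonics: Sequence[tuple[int, float, float]] = DEFAULT_HARMONICS,
    n_samples: int = 100,
) -> FlowWaveform:
    """Build a zero-mean periodic waveform from harmonic content.

    ``harmonics`` is a sequence of (n, amplitude mL/s, phase rad) adding
    ``a * sin(n w0 t + phase)``.  When ``stroke_volume`` (mL) is given the
    waveform is rescaled so the caudal (negative) phase carries exactly
    that volume; otherwise amplitudes are taken literally.
    """
    if n_samples < 16:
        raise SyntheticError("n_samples < 16 cannot represent 8 Hz content "
                             "at cardiac periods")
    if not harmonics or all(a == 0 for _, a, _ in harmonics):
        raise SyntheticError("at least one nonzero harmonic is required")
    t = np.arange(n_samples) * period / n_samples
    w0 = 2.0 * math.pi / period
    q = np.zeros(n_samples)
    for n, amp, phase in harmonics:
        if n < 1:
            raise SyntheticError("harmonic index must be >= 1")
        q += amp * np.sin(n * w0 * t + phase)
    wf = FlowWaveform(period, q)
    if stroke_volume is not None:
        sv = wf.stroke_volume()
        if sv <= 0:
            raise SyntheticError("waveform has no caudal phase to scale")
        wf = FlowWaveform(period, q * (stroke_volume / sv))
    return wf


@dataclass(frozen=True)
class Vortex:
    """Rankine vortex: solid-body core, 1/rho tail."""

    center: tuple[float, float]   # (x, z) mm
    peak_speed: float             # cm/s at the core radius
    core_radius: float            # mm


@dataclass
class SyntheticFieldSpec:
    """Recipe for a synthetic annular velocity field with known metrics."""

    r_inner: float = 4.0          # mm
    r_outer: float = 8.0          # mm
    spacing: float = 0.25         # in-plane grid spacing, mm
    y_positions: tuple = (0.0,)   # axial slice coordinates, mm
    axial_amplitude: float = 3.0  # cm/s
    axial_profile: str = "plug"   # plug | annular_poiseuille | none
    axial_time: str = "sin"       # sin | steady
    uniform_inplane: tuple[float, float] = (0.0, 0.0)  # cm/s
    vortices: tuple = ()          # of Vortex
    shedding_frequency: float = 0.0   # Hz
    shedding_amplitude: float = 0.0   # cm/s
    shedding_center: tuple[float, float] | None = None
    shedding_sigma: float = 1.0   # mm
    noise_sd: float = 0.0         # cm/s per component
    period: float = DEFAULT_PERIOD
    n_steps: int = 50
    n_cycles: int = 1
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.r_inner < self.r_outer:
            raise SyntheticError("need 0 <= r_inner < r_outer")
        for v in self.vortices:
            r = math.hypot(*v.center)
            if not (self.r_inner <= r <= self.r_outer):
                raise SyntheticError(
                    f"vortex core at {v.center} lies outside the annular mask")
        for name in ("axial_amplitude", "shedding_amplitude", "noise_sd"):
            if not np.isfinite(getattr(self, name)):
                raise SyntheticError(f"{name} must be finite")


@dataclass
class GroundTruth:
    """Analytic / dense-quadrature reference values for a synthetic field."""

    sfp_series: np.ndarray | None = None
    sfp_peak: float | None = None
    v_bi: float | None = None
    bi_duration: float | None = None
    peak_wss: float | None = None
    dominant_frequency_hz: float | None = None
    v_sys: float | None = None


def _annular_poiseuille_profile(r, ri, ro):
    """Normalized steady annulus profile (max value 1); plain plug if ri=0."""
    if ri == 0:
        return 1.0 - (r / ro) ** 2
    k = (ro**2 - ri**2) / math.log(ro / ri)
    u = ro**2 - r**2 + k * np.log(r / ro)
    rmax = math.sqrt(k / 2.0)
    umax = ro**2 - rmax**2 + k * math.log(rmax / ro)
    return u / umax


def _axial_shape(spec: SyntheticFieldSpec, r: np.ndarray) -> np.ndarray:
    if spec.axial_profile == "plug":
        return np.ones_like(r)
    if spec.axial_profile == "annular_poiseuille":
        return _annular_poiseuille_profile(r, spec.r_inner, spec.r_outer)
    if spec.axial_profile == "none":
        return np.zeros_like(r)
    raise SyntheticError(f"unknown axial profile {spec.axial_profile!r}")


def _axial_timefactor(spec: SyntheticFieldSpec, t: np.ndarray) -> np.ndarray:
    if spec.axial_time == "steady":
        return np.ones_like(t)
    if spec.axial_time == "sin":
        return np.sin(2.0 * math.pi * t / spec.period)
    raise SyntheticError(f"unknown axial time mode {spec.axial_time!r}")


def _inplane_velocity(spec: SyntheticFieldSpec, x, z):
    """Time-independent in-plane components (cm/s) at points (x, z)."""
    ux = np.full_like(x, spec.uniform_inplane[0])
    uz = np.full_like(z, spec.uniform_inplane[1])
    for v in spec.vortices:
        dx, dz = x - v.center[0], z - v.center[1]
        rho = np.hypot(dx, dz)
        with np.errstate(divide="ignore", invalid="ignore"):
            vt = np.where(rho <= v.core_radius,
                          v.peak_speed * rho / v.core_radius,
                          v.peak_speed * v.core_radius / np.maximum(rho, 1e-30))
            ex = np.where(rho > 0, -dz / np.maximum(rho, 1e-30), 0.0)
            ez = np.where(rho > 0, dx / np.maximum(rho, 1e-30), 0.0)
        ux = ux + vt * ex
        uz = uz + vt * ez
    return ux, uz


def _shedding_term(spec: SyntheticFieldSpec, x, z, t_scalar):
    if spec.shedding_amplitude == 0.0:
        return 0.0
    cx, cz = spec.shedding_center or (0.0, 0.5 * (spec.r_inner + spec.r_outer))
    rho2 = (x - cx) ** 2 + (z - cz) ** 2
    envelope = np.exp(-rho2 / (2.0 * spec.shedding_sigma**2))
    return (spec.shedding_amplitude
            * math.sin(2.0 * math.pi * spec.shedding_frequency * t_scalar)
            * envelope)


def _annulus_grid(spec: SyntheticFieldSpec, refine: int = 1):
    h = spec.spacing / refine
    n = int(np.ceil(2 * spec.r_outer / h)) + 1
    ax = np.linspace(-spec.r_outer, spec.r_outer, n)
    X, Z = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(X, Z)
    mask = (r >= spec.r_inner) & (r <= spec.r_outer)
    return X[mask], Z[mask], h


def _evaluate(spec: SyntheticFieldSpec, x, z, times, rng=None):
    """Closed-form field evaluation at in-plane points for all times."""
    r = np.hypot(x, z)
    shape = _axial_shape(spec, r)
    tf = _axial_timefactor(spec, times)
    ux0, uz0 = _inplane_velocity(spec, x, z)
    K, N = len(times), len(x)
    vel = np.zeros((K, N, 3))
    for k, t in enumerate(times):
        vel[k, :, 1] = spec.axial_amplitude * shape * tf[k]
        vel[k, :, 0] = ux0 + _shedding_term(spec, x, z, t)
        vel[k, :, 2] = uz0
    if rng is not None and spec.noise_sd > 0:
        vel += rng.normal(0.0, spec.noise_sd, size=vel.shape)
    return vel


def make_synthetic_field(spec: SyntheticFieldSpec) -> tuple[VelocityField, GroundTruth]:
    """Sample the specified field on its annular grid and derive ground truth.

    Ground-truth values are computed from the closed-form velocity
    definition on a grid refined 4x relative to the sampled field (dense
    quadrature), independently of the sampled arrays, and exclude noise.
    """
    x, z, h = _annulus_grid(spec)
    K = spec.n_steps * spec.n_cycles
    times = np.arange(K) * spec.period / spec.n_steps
    rng = np.random.default_rng(spec.seed)
    ny = len(spec.y_positions)
    pts_list, vel_list, w_list = [], [], []
    vel2d = _evaluate(spec, x, z, times, rng=None)
    for y in spec.y_positions:
        pts = np.column_stack([x, np.full_like(x, y), z])
        pts_list.append(pts)
        vel_list.append(vel2d)
        w_list.append(np.full_like(x, h * h))
    points = np.vstack(pts_list)
    velocity = np.concatenate(vel_list, axis=1)
    # weights: nodal area (single slice) or volume share across slices
    dy = 1.0 if ny == 1 else (max(spec.y_positions) - min(spec.y_positions)) / max(ny - 1, 1)
    weights = np.concatenate(w_list) * (1.0 if ny == 1 else dy)
    if spec.noise_sd > 0:
        velocity = velocity + rng.normal(0.0, spec.noise_sd, size=velocity.shape)
    fld = VelocityField(
        points=points, times=times, velocity=velocity, weights=weights,
        period=spec.period,
        attrs={"r_inner": spec.r_inner, "r_outer": spec.r_outer,
               "spacing": h, "kind": "synthetic-annulus"},
    )

    gt = _ground_truth(spec, times)
    return fld, gt


def _ground_truth(spec: SyntheticFieldSpec, times: np.ndarray) -> GroundTruth:
    xq, zq, _ = _annulus_grid(spec, refine=4)
    vel = _evaluate(spec, xq, zq, times, rng=None)
    inplane = np.hypot(vel[:, :, 0], vel[:, :, 2])
    speed = np.linalg.norm(vel, axis=2)
    num = inplane.sum(axis=1)
    den = speed.sum(axis=1)
    sfp = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    axial = vel[:, :, 1]
    vmax = axial.max(axis=1)
    vmin = axial.min(axis=1)
    b = np.where((vmax > 0) & (vmin < 0), vmax - vmin, 0.0)
    dt = times[1] - times[0] if len(times) > 1 else 0.0
    threshold = 0.1  # cm/s = 1 mm/s
    if spec.shedding_amplitude > 0:
        dom = spec.shedding_frequency
    elif spec.axial_time == "sin":
        dom = 1.0 / spec.period
    else:
        dom = 0.0
    peak_wss = None
    if spec.axial_profile == "annular_poiseuille":
        # exact wall-gradient magnitude of the normalized profile at r_outer
        ri, ro = spec.r_inner, spec.r_outer
        k = (ro**2 - ri**2) / math.log(ro / ri)
        rmax = math.sqrt(k / 2.0)
        umax = ro**2 - rmax**2 + k * math.log(rmax / ro)
        slope_o = abs((-2.0 * ro + k / ro) / umax)      # 1/mm, normalized
        slope_i = abs((-2.0 * ri + k / ri) / umax)
        tfmax = np.max(np.abs(_axial_timefactor(spec, times)))
        # shear rate: cm/s per mm = 10 1/s; times mu (water at 37 C) -> Pa
        rate = spec.axial_amplitude * max(slope_o, slope_i) * tfmax * 10.0
        peak_wss = float(rate * DEFAULT_VISCOSITY)
    t_sys = times[np.argmin(np.sin(2 * math.pi * times / spec.period))] \
        if spec.axial_time == "sin" else times[0]
    k_sys = int(np.argmin(np.abs(times - t_sys)))
    return GroundTruth(
        sfp_series=sfp,
        sfp_peak=float(sfp.max()) if len(sfp) else None,
        v_bi=float(b.max()),
        bi_duration=float(np.sum(b > threshold) * dt),
        peak_wss=peak_wss,
        dominant_frequency_hz=dom,
        v_sys=float(speed[k_sys].max()),
    )
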
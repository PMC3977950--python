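"""Integrated longitudinal impedance (ILI) via Fourier decomposition.

Longitudinal impedance quantifies the resistance a conduit opposes to
pulsatile flow.  For a periodic flow waveform Q(t) and the pressure drop
dP(t) across a segment, both sampled over one cycle, the harmonic moduli

    |Z_n| = |dP_n| / |Q_n|,       n = 1, 2, ...

are formed from the discrete Fourier coefficients, and the integrated
value is their sum over the cardiac harmonics up to a frequency cap
(8 Hz by convention in CSF and hemodynamic work):

    Z_L = sum_{n >= 1, f_n <= f_max} |Z_n|.

Being the impedance of a linear system, Z_L is invariant under scaling of
the waveform amplitude.  Internally SI (Pa.s/m^3); tables report the
hemodynamic unit dyn.s/cm^5 (1 Pa.s/m^3 = 1e-5 dyn.s/cm^5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PA_S_PER_M3_TO_DYN_S_PER_CM5 = 1e-5

DEFAULT_F_MAX = 8.0          # Hz
DEFAULT_Q_FLOOR = 1e-8       # relative |Q_n| floor guarding the division


class ImpedanceError(ValueError):
    pass


@dataclass
class ImpedanceSpectrum:
    """Per-harmonic impedance moduli and their sum."""

    fundamental_hz: float
    harmonics: np.ndarray        # harmonic indices n
    frequencies_hz: np.ndarray
    Q_n: np.ndarray              # complex, mL/s
    dP_n: np.ndarray             # complex, Pa
    Z_n: np.ndarray              # moduli, dyn.s/cm^5
    n_excluded: int = 0          # harmonics dropped by the |Q_n| floor

    @property
    def Z_L(self) -> float:
        """Integrated longitudinal impedance, dyn.s/cm^5."""
        return float(np.sum(self.Z_n))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "n": self.harmonics,
            "f_Hz": self.frequencies_hz,
            "abs_Q_n_mL_s": np.abs(self.Q_n),
            "abs_dP_n_Pa": np.abs(self.dP_n),
            "Z_n_dyne_cm5": self.Z_n,
        })
        return df


def _one_sided(x: np.ndarray) -> np.ndarray:
    n = len(x)
    c = np.fft.rfft(x) / n
    out = 2.0 * c
    out[0] = c[0]
    if n % 2 == 0:
        out[-1] = c[-1]
    return out


def longitudinal_impedance(
    q: np.ndarray, dp: np.ndarray, period: float,
    f_max: float = DEFAULT_F_MAX,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> ImpedanceSpectrum:
    """Impedance spectrum of one segment.

    ``q`` (mL/s) and ``dp`` (Pa) must be sampled on the same uniform grid
    over exactly one flow cycle of length ``period`` (s).  Harmonics are
    the multiples of the cardiac fundamental 1/T with f_n <= f_max;
    harmonics whose |Q_n| falls below ``q_floor`` times the largest |Q_n|
    are excluded (counted, not silently dropped) to avoid dividing by a
    vanishing flow coefficient.
    """
    q = np.asarray(q, dtype=float)
    dp = np.asarray(dp, dtype=float)
    if q.shape != dp.shape or q.ndim != 1:
        raise ImpedanceError("Q and dP must share one uniform sampling grid")
    if period <= 0:
        raise ImpedanceError("period must be positive")
    qn = _one_sided(q)
    dpn = _one_sided(dp)
    f0 = 1.0 / period
    n_idx = np.arange(1, len(qn))
    n_idx = n_idx[n_idx * f0 <= f_max + 1e-12]
    if len(n_idx) == 0:
        raise ImpedanceError("no harmonics at or below f_max")
    qmax = np.max(np.abs(qn[n_idx]))
    keep = np.abs(qn[n_idx]) > q_floor * qmax
    n_excluded = int(np.sum(~keep))
    n_idx = n_idx[keep]
    if len(n_idx) == 0:
        raise ImpedanceError("all harmonics excluded by the |Q_n| floor")
    # mL/s -> m^3/s; moduli in Pa.s/m^3, reported in dyn.s/cm^5
    z_si = np.abs(dpn[n_idx]) / (np.abs(qn[n_idx]) * 1e-6)
    return ImpedanceSpectrum(
        fundamental_hz=f0,
        harmonics=n_idx,
        frequencies_hz=n_idx * f0,
        Q_n=qn[n_idx],
        dP_n=dpn[n_idx],
        Z_n=z_si * PA_S_PER_M3_TO_DYN_S_PER_CM5,
        n_excluded=n_excluded,
    )


def ili_pipeline(geometry, waveform, fluid,
                 mesh_level: str = "medium",
                 n_steps: int = 100,
                 f_max: float = DEFAULT_F_MAX,
                 solutions: dict | None = None) -> pd.DataFrame:
    """Per-segment integrated longitudinal impedance for a geometry.

    Runs the oscillatory solver on every station (or reuses ``solutions``),
    forms segment pressure-drop traces, and computes Z_L per segment and
    for the whole model, keyed like the per-segment results tables.
    """
    from .solver import segment_pressure_traces, solve_geometry

    if solutions is None:
        solutions = solve_geometry(geometry, fluid, waveform,
                                   mesh_level=mesh_level)
    traces = segment_pressure_traces(solutions, geometry, n_steps=n_steps)
    q = waveform.evaluate(traces["t_s"].to_numpy())
    rows = []
    for col in traces.columns:
        if col == "t_s":
            continue
        spec = longitudinal_impedance(q, traces[col].to_numpy(),
                                      waveform.period, f_max=f_max)
        rows.append({"segment": col, "Z_L_dyne_cm5": spec.Z_L,
                     "n_harmonics": len(spec.harmonics),
                     "n_excluded": spec.n_excluded})
    return pd.DataFrame(rows)
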
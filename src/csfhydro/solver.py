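"""Per-harmonic oscillatory axial flow on SSS cross-sections.

The flow is modeled as laminar, fully developed oscillatory flow of an
incompressible Newtonian fluid: for each cardiac harmonic n with angular
frequency w_n = n w0, the complex axial velocity amplitude u_n(x, z)
satisfies the unsteady-Stokes (complex Helmholtz) problem

    (i w_n / nu) u_n - lap(u_n) = G_n / mu,     u_n = 0 on all walls,

where G_n = -dP/dy is the complex axial pressure-gradient amplitude.  The
problem is linear, so it is solved once per harmonic with unit forcing and
G_n is then fixed by flux matching: the sectional flux of u_n must equal
the waveform harmonic Q_n.  At w = 0 the problem reduces to steady
Poiseuille flow in the section.

This is a Womersley-type generalization to arbitrary multiply-connected
cross-sections, discretized with P1 finite elements.  It omits convective
acceleration and axial development, which is the appropriate desk-scale
model at the low Reynolds numbers of cervical CSF flow; fully 3D effects
(secondary flow, vortex shedding) enter the pipeline through imported or
synthetic fields instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.linalg import splu

from .anatomy import CrossSection, GeometryModel
from .fieldio import VelocityField
from .fluid import CSF, FluidProperties
from .mesh import TriMesh, assemble_p1, triangulate
from .synthetic import FlowWaveform

#: Default mesh spacings, mm, graded geometrically from the walls; chosen
#: so the per-harmonic solve resolves the oscillatory (Stokes) boundary
#: layer of cardiac-frequency CSF flow to sub-0.1% L2 accuracy.
DEFAULT_H_WALL = 0.025
DEFAULT_H_CORE = 0.1
DEFAULT_GROWTH = 1.12

#: Coarser named levels for whole-geometry runs and independence ladders.
MESH_LEVELS = {
    "coarse": (0.12, 0.5, 1.5),
    "medium": (0.08, 0.35, 1.3),
    "fine": (0.05, 0.2, 1.2),
}

#: Default number of time steps per flow cycle (T/100).
DEFAULT_N_STEPS = 100


class SolverError(RuntimeError):
    pass


def mesh_section(section: CrossSection,
                 h_wall: float = DEFAULT_H_WALL,
                 h_core: float = DEFAULT_H_CORE,
                 growth: float = DEFAULT_GROWTH) -> TriMesh:
    """Triangulate a cross-section's lumen for the P1 solve."""
    return triangulate(section.lumen, h_wall=h_wall, h_core=h_core,
                       growth=growth)


def womersley_number(section: CrossSection, fluid: FluidProperties,
                     omega: float) -> float:
    """alpha = (D_h / 2) sqrt(omega / nu); 0 at omega = 0."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    dh_m = section.hydraulic_diameter * 1e-3
    return 0.5 * dh_m * math.sqrt(omega / fluid.kinematic_viscosity)


@dataclass
class HarmonicSolution:
    """Flux-matched complex axial velocity for one harmonic."""

    n: int                      # harmonic index (0 = steady)
    omega: float                # rad/s
    u: np.ndarray               # complex nodal axial velocity, m/s
    G: complex                  # axial pressure-gradient amplitude, Pa/m
    Q: complex                  # matched flux harmonic, mL/s
    alpha: float                # Womersley number


@dataclass
class _Operator:
    """Factorized P1 operator for one mesh (shared across harmonics)."""

    mesh: TriMesh
    K: object
    M_si: object
    b: np.ndarray               # load vector int(phi_i) dA, m^2
    free: np.ndarray            # interior-node mask

    @classmethod
    def build(cls, mesh: TriMesh) -> "_Operator":
        K, M_mm = assemble_p1(mesh)
        M_si = M_mm * 1e-6                        # mm^2 -> m^2
        b = np.asarray(M_si.sum(axis=1)).ravel()
        free = ~mesh.boundary
        if free.sum() == 0:
            raise SolverError("mesh has no interior degrees of freedom")
        return cls(mesh=mesh, K=K, M_si=M_si, b=b, free=free)


def _solve_unit(op: _Operator, fluid: FluidProperties, omega: float) -> np.ndarray:
    """Solve with unit pressure gradient G = 1 Pa/m; return nodal u (m/s)."""
    nu = fluid.kinematic_viscosity
    mu = fluid.dynamic_viscosity
    f = op.free
    A = (op.K + (1j * omega / nu) * op.M_si if omega > 0
         else op.K.astype(float)).tocsc()[f][:, f]
    rhs = (op.b[f] / mu).astype(A.dtype)
    u = np.zeros(op.mesh.n_nodes, dtype=A.dtype)
    u[f] = splu(A.tocsc()).solve(rhs)
    return u


def solve_harmonic(section: CrossSection, fluid: FluidProperties,
                   omega: float, Q_n: complex,
                   mesh: TriMesh | None = None,
                   n: int | None = None) -> HarmonicSolution:
    """Solve one harmonic on a section, flux-matched to Q_n (mL/s).

    Returns the nodal complex velocity (m/s, zero on every boundary node)
    and the pressure-gradient amplitude G_n (Pa/m) such that the sectional
    flux equals Q_n.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    msh = mesh if mesh is not None else mesh_section(section)
    op = _Operator.build(msh)
    return _solve_harmonic_op(section, op, fluid, omega, Q_n, n=n)


def _solve_harmonic_op(section, op: _Operator, fluid, omega, Q_n,
                       n=None) -> HarmonicSolution:
    alpha = womersley_number(section, fluid, omega)
    if Q_n == 0:
        z = np.zeros(op.mesh.n_nodes, dtype=complex)
        return HarmonicSolution(n=n or 0, omega=omega, u=z, G=0.0 + 0.0j,
                                Q=0.0 + 0.0j, alpha=alpha)
    u_unit = _solve_unit(op, fluid, omega)
    flux_unit = op.b @ u_unit                     # m^3/s per unit G
    if abs(flux_unit) == 0:
        raise SolverError("zero conductance: cannot match a nonzero flux")
    G = (Q_n * 1e-6) / flux_unit                  # Pa/m
    u = u_unit * G
    return HarmonicSolution(n=n if n is not None else 0, omega=omega,
                            u=u.astype(complex), G=complex(G),
                            Q=complex(Q_n), alpha=alpha)


@dataclass
class SectionSolution:
    """All harmonics of a waveform solved on one section."""

    section: CrossSection
    mesh: TriMesh
    fluid: FluidProperties
    waveform: FlowWaveform
    harmonics: list = field(default_factory=list)   # of HarmonicSolution
    node_area: np.ndarray = None                    # mm^2 per node

    @property
    def omega0(self) -> float:
        return self.waveform.omega0

    def pressure_gradient(self, times: np.ndarray) -> np.ndarray:
        """Real axial pressure gradient G(t) = -dP/dy, Pa/m."""
        out = np.zeros_like(np.asarray(times, dtype=float))
        for h in self.harmonics:
            out = out + np.real(h.G * np.exp(1j * h.omega * times))
        return out

    def velocity(self, times: np.ndarray) -> np.ndarray:
        """Real nodal axial velocity (K, N), m/s."""
        times = np.asarray(times, dtype=float)
        out = np.zeros((len(times), self.mesh.n_nodes))
        for h in self.harmonics:
            out += np.real(np.exp(1j * h.omega * times)[:, None] * h.u[None, :])
        return out

    def flux(self, times: np.ndarray) -> np.ndarray:
        """Sectional flux (mL/s) of the reconstructed field."""
        # m/s times mm^2 is 1e-6 m^3/s, i.e. numerically mL/s already
        return self.velocity(times) @ self.node_area

    def time_domain(self, n_steps: int = DEFAULT_N_STEPS,
                    n_cycles: int = 1, y: float = 0.0) -> VelocityField:
        """Sample the harmonic sum on a uniform time grid as a VelocityField."""
        T = self.waveform.period
        K = n_steps * n_cycles
        times = np.arange(K) * T / n_steps
        v = self.velocity(times) * 100.0           # m/s -> cm/s
        N = self.mesh.n_nodes
        pts = np.column_stack([
            self.mesh.points[:, 0],
            np.full(N, y),
            self.mesh.points[:, 1],
        ])
        vel = np.zeros((K, N, 3))
        vel[:, :, 1] = v
        return VelocityField(
            points=pts, times=times, velocity=vel,
            weights=self.node_area, period=T,
            attrs={"kind": "solver-planar", "station": self.section.station},
        )


def solve_waveform(section: CrossSection, fluid: FluidProperties,
                   waveform: FlowWaveform,
                   mesh: TriMesh | None = None,
                   f_max: float | None = None,
                   rel_floor: float = 1e-9,
                   h_wall: float = DEFAULT_H_WALL,
                   h_core: float = DEFAULT_H_CORE,
                   growth: float = DEFAULT_GROWTH) -> SectionSolution:
    """Solve every significant harmonic of a waveform on one section.

    Harmonics with |Q_n| below ``rel_floor`` times the largest modulus are
    skipped (they contribute nothing and would waste solves); ``f_max``
    optionally caps the solved band, otherwise the full Nyquist content of
    the sampled waveform is used.
    """
    msh = mesh if mesh is not None else mesh_section(section, h_wall, h_core, growth)
    op = _Operator.build(msh)
    q = waveform.coefficients()
    qmax = np.max(np.abs(q))
    if qmax == 0:
        raise SolverError("waveform is identically zero")
    sols = []
    w0 = waveform.omega0
    f0 = 1.0 / waveform.period
    for n_idx in range(len(q)):
        if abs(q[n_idx]) <= rel_floor * qmax:
            continue
        if f_max is not None and n_idx * f0 > f_max:
            continue
        sols.append(_solve_harmonic_op(section, op, fluid, n_idx * w0,
                                       q[n_idx], n=n_idx))
    node_area = op.b * 1e6                         # m^2 -> mm^2
    return SectionSolution(section=section, mesh=msh, fluid=fluid,
                           waveform=waveform, harmonics=sols,
                           node_area=node_area)


def solve_geometry(geometry: GeometryModel, fluid: FluidProperties,
                   waveform: FlowWaveform,
                   mesh_level: str = "medium",
                   f_max: float | None = None) -> dict:
    """Solve the waveform on every station section.

    Whole-geometry runs default to the coarser named "medium" mesh level:
    the quantities derived from them (directional with/without-NRDL deltas,
    impedance moduli) are far less resolution-sensitive than the
    per-harmonic profile itself.
    """
    hw, hc, g = MESH_LEVELS[mesh_level]
    return {st: solve_waveform(geometry.sections[st], fluid, waveform,
                               f_max=f_max, h_wall=hw, h_core=hc, growth=g)
            for st in geometry.stations}


def segment_pressure_traces(solutions: dict, geometry: GeometryModel,
                            n_steps: int = DEFAULT_N_STEPS,
                            n_cycles: int = 1) -> pd.DataFrame:
    """Per-segment pressure-drop traces dP(t) = G(t) * L, Pa.

    Each segment uses the solve of its cranial bounding station
    (piecewise-uniform approximation); the whole-model trace is the sum of
    the segment traces (telescoping).
    """
    wf = next(iter(solutions.values())).waveform
    T = wf.period
    times = np.arange(n_steps * n_cycles) * T / n_steps
    data = {"t_s": times}
    for seg in geometry.segments:
        up, _ = seg
        L = geometry.segment_length(seg) * 1e-3    # mm -> m
        data[f"{seg[0]}-{seg[1]}"] = solutions[up].pressure_gradient(times) * L
    df = pd.DataFrame(data)
    seg_cols = [c for c in df.columns if c != "t_s"]
    df["FM-C7"] = df[seg_cols].sum(axis=1)
    return df


def assemble_time_domain(solution: SectionSolution,
                         n_steps: int = DEFAULT_N_STEPS,
                         n_cycles: int = 1) -> tuple[VelocityField, np.ndarray]:
    """Time-sample one section solution.

    Returns the VelocityField over the requested cycles and the pressure
    gradient per unit length G(t) (Pa/m) on the same time grid.  The
    harmonic sum is exactly periodic, so any cycle equals the first.
    """
    fld = solution.time_domain(n_steps=n_steps, n_cycles=n_cycles)
    g = solution.pressure_gradient(fld.times)
    return fld, g
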
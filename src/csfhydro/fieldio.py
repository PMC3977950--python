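"""Time-resolved velocity-field container and on-disk fixtures.

A :class:`VelocityField` holds node coordinates (mm), uniform time samples
over an integer number of flow cycles, velocity vectors (cm/s) and
per-node quadrature weights, together with the axial-direction convention
(axial = y, positive cranial; caudal flow is negative).

Fixtures are written as a *VTK series*: one legacy-VTK ASCII POLYDATA file
per time step plus a JSON index carrying times, period, weights and the
axial convention.  Floats are serialized with 17 significant digits, so a
write/read round trip is bit-exact for float64 data.  The writer/reader is
minimal and self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AXIAL_AXIS = 1  # y

FMT = "%.17g"


class FieldIOError(ValueError):
    """Malformed or incomplete field fixture."""


@dataclass
class VelocityField:
    """Sampled velocity field: points (N,3) mm, times (K,) s, velocity (K,N,3) cm/s."""

    points: np.ndarray
    times: np.ndarray
    velocity: np.ndarray
    weights: np.ndarray          # (N,) quadrature weights, mm^2 (planar) or mm^3
    period: float                # flow-cycle length T, s
    axial: str = "y+cranial"     # direction convention flag; required on read
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        K, N = len(self.times), len(self.points)
        if self.velocity.shape != (K, N, 3):
            raise FieldIOError(
                f"velocity shape {self.velocity.shape} != ({K}, {N}, 3)")
        if self.weights.shape != (N,):
            raise FieldIOError("weights must be one scalar per node")
        if K > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise FieldIOError("time samples must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def axial_velocity(self) -> np.ndarray:
        """Signed axial component, (K, N), cm/s (negative = caudal)."""
        return self.velocity[:, :, AXIAL_AXIS]

    @property
    def inplane_speed(self) -> np.ndarray:
        v = self.velocity
        return np.hypot(v[:, :, 0], v[:, :, 2])

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=2)

    def flux(self) -> np.ndarray:
        """Signed axial volumetric flux per time step, mL/s.

        Valid for planar fields whose weights are nodal areas in mm^2:
        mm^2 * cm/s = 1e-2 cm^3/s.
        """
        return (self.axial_velocity @ self.weights) * 1e-2


def _write_vtk_polydata(path: Path, points: np.ndarray, vectors: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("csfhydro velocity field\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} double\n")
        np.savetxt(fh, points, fmt=FMT)
        fh.write(f"POINT_DATA {len(points)}\n")
        fh.write("VECTORS velocity double\n")
        np.savetxt(fh, vectors, fmt=FMT)


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        ip = next(i for i, l in enumerate(lines) if l.startswith("POINTS"))
        npts = int(lines[ip].split()[1])
        pts = np.loadtxt(lines[ip + 1: ip + 1 + npts])
        iv = next(i for i, l in enumerate(lines) if l.startswith("VECTORS"))
        vec = np.loadtxt(lines[iv + 1: iv + 1 + npts])
    except (StopIteration, ValueError) as exc:
        raise FieldIOError(f"malformed VTK file {path}: {exc}") from exc
    return pts.reshape(npts, 3), vec.reshape(npts, 3)


def write_fixture(fld: VelocityField, path) -> None:
    """Write a field as a legacy-VTK ASCII series with a JSON index."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    steps = []
    for k in range(len(fld.times)):
        name = f"step_{k:04d}.vtk"
        _write_vtk_polydata(path / name, fld.points, fld.velocity[k])
        steps.append(name)
    index = {
        "format": "csfhydro-vtk-series/1",
        "axial": fld.axial,
        "period_s": float(fld.period),
        "times_s": [float(FMT % t) for t in fld.times],
        "times_hex": [float(t).hex() for t in fld.times],
        "weights_hex": [float(w).hex() for w in fld.weights],
        "files": steps,
        "attrs": {k: v for k, v in fld.attrs.items()
                  if isinstance(v, (int, float, str, bool, list))},
    }
    (path / "index.json").write_text(json.dumps(index, indent=1))


def read_fixture(path) -> VelocityField:
    """Read a field fixture written by :func:`write_fixture`.

    The axial-direction convention flag must be present; it is never
    silently assumed.  Time metadata is likewise required.
    """
    path = Path(path)
    idx_path = path / "index.json"
    if not idx_path.exists():
        raise FieldIOError(f"no index.json under {path}")
    index = json.loads(idx_path.read_text())
    if "axial" not in index or not index["axial"]:
        raise FieldIOError("fixture lacks the axial-direction convention flag")
    if "times_hex" not in index and "times_s" not in index:
        raise FieldIOError("fixture lacks time metadata")
    times = np.array([float.fromhex(h) for h in index["times_hex"]])
    weights = np.array([float.fromhex(h) for h in index["weights_hex"]])
    pts = None
    vels = []
    for name in index["files"]:
        p, v = _read_vtk_polydata(path / name)
        pts = p if pts is None else pts
        vels.append(v)
    return VelocityField(
        points=pts, times=times, velocity=np.stack(vels), weights=weights,
        period=float(index["period_s"]), axial=index["axial"],
        attrs=index.get("attrs", {}),
    )
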
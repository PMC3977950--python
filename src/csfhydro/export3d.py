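"""3D surface export of the idealized SSS geometry.

Lofts the dura and cord station circles into triangulated tubes and
extrudes each NRDL obstruction footprint into a prism at its station
plane, writing STL (binary via trimesh) or legacy-VTK ASCII polydata.
Dorsal nerve-root prisms optionally carry a sinusoidal radial perturbation
mimicking the rootlet ridges; in 2D sections the ridges are metadata only,
below section-plane resolution.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import trimesh

from .anatomy import GeometryModel

RIDGE_AMPLITUDE = 0.05   # mm
RIDGE_WAVELENGTH = 0.5   # mm


def _loft_rings(rings: list[np.ndarray]) -> trimesh.Trimesh:
    """Triangulate between consecutive rings of equal point count."""
    n = len(rings[0])
    verts = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        base = k * n
        for i in range(n):
            a, b = base + i, base + (i + 1) % n
            c, d = a + n, b + n
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def _station_ring(radius: float, y: float, center=(0.0, 0.0),
                  n: int = 96) -> np.ndarray:
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    x = center[0] + radius * np.cos(th)
    z = center[1] + radius * np.sin(th)
    return np.column_stack([x, np.full(n, y), z])


def _obstruction_prism(poly, y: float, thickness: float,
                       ridged: bool = False) -> trimesh.Trimesh:
    """Loft a footprint boundary into an open-sided prism on the plane."""
    ring = poly.exterior
    n = max(int(ring.length / 0.3), 16)
    import shapely
    s = np.linspace(0, ring.length, n, endpoint=False)
    pts = shapely.line_interpolate_point(ring, s)
    xz = np.array([[p.x, p.y] for p in pts])
    if ridged:
        # sinusoidal radial perturbation mimicking the dorsal rootlet ridges
        r = np.hypot(xz[:, 0], xz[:, 1])
        xz *= (1.0 + RIDGE_AMPLITUDE / np.maximum(r[:, None], 1e-9)
               * np.sin(2 * math.pi * r[:, None] / RIDGE_WAVELENGTH))
    rings = [np.column_stack([xz[:, 0], np.full(n, yy), xz[:, 1]])
             for yy in (y - thickness / 2, y + thickness / 2)]
    return _loft_rings(rings)


def geometry_surfaces(geometry: GeometryModel) -> trimesh.Trimesh:
    """Lofted dura + cord tubes and NRDL prisms as one mesh."""
    dura_rings, cord_rings = [], []
    for st in geometry.stations:
        sec = geometry.sections[st]
        y = geometry.axial_positions[st]
        p = sec.params
        dura_rings.append(_station_ring(p.dura_radius, y))
        cord_rings.append(_station_ring(p.cord_radius, y,
                                        center=(0.0, p.eccentricity)))
    parts = [_loft_rings(dura_rings), _loft_rings(cord_rings)]
    for st in geometry.stations:
        sec = geometry.sections[st]
        y = geometry.axial_positions[st]
        ridged_specs = {id(s) for s in sec.rootlet_ridges}
        for fp in sec.obstructions:
            polys = fp.geoms if hasattr(fp, "geoms") else [fp]
            for poly in polys:
                if poly.area <= 0:
                    continue
                parts.append(_obstruction_prism(
                    poly, y, thickness=1.0,
                    ridged=bool(ridged_specs)))
    return trimesh.util.concatenate(parts)


def export_stl(geometry: GeometryModel, path) -> Path:
    """Write the lofted model as an STL file."""
    path = Path(path)
    geometry_surfaces(geometry).export(path, file_type="stl")
    return path


def export_vtk(geometry: GeometryModel, path) -> Path:
    """Write the lofted model as legacy-VTK ASCII polydata."""
    mesh = geometry_surfaces(geometry)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("csfhydro geometry surfaces\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.9g")
        f = mesh.faces
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")
    return path
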
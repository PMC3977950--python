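"""Triangulation of planar, multiply-connected cross-sections.

Cross-sections of the spinal subarachnoid space are annular regions with
holes (cord, nerve roots, ligaments).  They are represented as shapely
polygons and meshed with linear (P1) triangles by Delaunay triangulation of
a graded point cloud: densely sampled boundary rings, one or two offset
rings just inside each wall, and a hexagonal core lattice.  Triangles whose
centroid falls outside the polygon are discarded, which resolves holes and
concavities without a constrained mesher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csr_matrix
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPolygon, Polygon


class MeshError(ValueError):
    """Raised for degenerate or disconnected meshes."""


def _cross2(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """z-component of the cross product of planar vectors."""
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


@dataclass
class TriMesh:
    """P1 triangle mesh of a planar region.

    Coordinates are in millimetres.  ``boundary`` flags nodes that lie on a
    wall (Dirichlet nodes for the no-slip solve); ``boundary_normals`` holds
    the inward unit normal at each boundary node (zeros elsewhere).
    """

    points: np.ndarray          # (N, 2) mm
    triangles: np.ndarray       # (M, 3) int
    boundary: np.ndarray        # (N,) bool
    boundary_normals: np.ndarray = field(default=None)  # (N, 2)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def areas(self) -> np.ndarray:
        """Signed triangle areas (mm^2); positive for CCW orientation."""
        p = self.points
        a, b, c = (p[self.triangles[:, k]] for k in range(3))
        return 0.5 * _cross2(b - a, c - a)

    def total_area(self) -> float:
        return float(np.sum(self.areas))


def _ring_points(ring, spacing: float) -> np.ndarray:
    """Sample a shapely LinearRing at approximately uniform arc spacing."""
    length = ring.length
    n = max(int(np.ceil(length / spacing)), 8)
    s = np.linspace(0.0, length, n, endpoint=False)
    pts = shapely.line_interpolate_point(ring, s)
    return np.array([[p.x, p.y] for p in pts])


def _polygon_parts(polygon) -> list[Polygon]:
    if isinstance(polygon, MultiPolygon):
        return list(polygon.geoms)
    return [polygon]


def triangulate(polygon, h_wall: float = 0.2, h_core: float = 0.4,
                growth: float = 1.5) -> TriMesh:
    """Mesh a (multi)polygon with graded linear triangles.

    Parameters
    ----------
    polygon : shapely Polygon or MultiPolygon
        Region to mesh, in mm.
    h_wall : float
        Target boundary edge length (mm); also the offset of the near-wall
        point layers used to resolve the viscous boundary layer.
    h_core : float
        Target interior lattice spacing (mm).
    growth : float
        Geometric growth factor of the near-wall layer spacing; smaller
        values grade more gently (more layers) from h_wall to h_core.
    """
    if polygon.is_empty or polygon.area <= 0:
        raise MeshError("cannot mesh an empty or zero-area section")

    bnd_pts: list[np.ndarray] = []
    bnd_normals: list[np.ndarray] = []
    for part in _polygon_parts(polygon):
        for ring, inward_sign in [(part.exterior, 1.0)] + [
            (r, -1.0) for r in part.interiors
        ]:
            pts = _ring_points(ring, h_wall)
            # tangent by wrapped central difference, normal = rotated tangent
            nxt = np.roll(pts, -1, axis=0)
            prv = np.roll(pts, 1, axis=0)
            tang = nxt - prv
            tang /= np.linalg.norm(tang, axis=1, keepdims=True)
            nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
            # shapely exteriors are CCW, interiors CW: rotating the tangent
            # by +90 deg then points inward for exteriors and into the lumen
            # for interiors alike when rings follow shapely's orientation
            # convention; fix sign by probing.
            probe = pts + 0.25 * h_wall * nrm
            inside = shapely.contains_xy(polygon, probe[:, 0], probe[:, 1])
            nrm[~inside] *= -1.0
            bnd_pts.append(pts)
            bnd_normals.append(nrm)

    boundary_pts = np.vstack(bnd_pts)
    boundary_nrm = np.vstack(bnd_normals)
    n_bnd = len(boundary_pts)

    interior: list[np.ndarray] = []
    # near-wall offset layers: spacing grows geometrically from h_wall to
    # h_core so the oscillatory (Stokes) boundary layer is resolved without
    # a uniformly fine mesh
    d, s = h_wall, h_wall
    layer_spacings = []
    while s < h_core:
        layer_spacings.append((d, s))
        s *= growth
        d += min(s, h_core)
    d_last = layer_spacings[-1][0] if layer_spacings else 0.0
    for d, s in layer_spacings:
        shrunk = polygon.buffer(-d)
        if shrunk.is_empty:
            continue
        for part in _polygon_parts(shrunk):
            for ring in [part.exterior] + list(part.interiors):
                interior.append(_ring_points(ring, 1.2 * s))

    # hexagonal core lattice
    minx, miny, maxx, maxy = polygon.bounds
    dy = h_core * np.sqrt(3.0) / 2.0
    rows = []
    y = miny
    row = 0
    while y <= maxy:
        xs = np.arange(minx + (0.5 * h_core if row % 2 else 0.0), maxx + h_core, h_core)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        row += 1
    lattice = np.vstack(rows) if rows else np.empty((0, 2))
    core_region = polygon.buffer(-(d_last + 0.6 * h_core))
    if not core_region.is_empty and len(lattice):
        keep = shapely.contains_xy(core_region, lattice[:, 0], lattice[:, 1])
        interior.append(lattice[keep])

    pts_all = [boundary_pts]
    occupied = boundary_pts
    for chunk in interior:
        if not len(chunk):
            continue
        tree = cKDTree(occupied)
        d, _ = tree.query(chunk)
        chunk = chunk[d > 0.55 * h_wall]
        if len(chunk):
            pts_all.append(chunk)
            occupied = np.vstack([occupied, chunk])

    points = np.vstack(pts_all)
    if len(points) < 4:
        raise MeshError("too few mesh points; refine spacing")

    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(polygon, cent[:, 0], cent[:, 1])
    simplices = tri.simplices[keep]

    # drop degenerate slivers
    a, b, c = (points[simplices[:, k]] for k in range(3))
    area2 = _cross2(b - a, c - a)
    simplices = simplices[np.abs(area2) > 1e-12]
    # enforce CCW
    a, b, c = (points[simplices[:, k]] for k in range(3))
    flip = _cross2(b - a, c - a) < 0
    simplices[flip] = simplices[flip][:, ::-1]

    used = np.unique(simplices)
    remap = -np.ones(len(points), dtype=int)
    remap[used] = np.arange(len(used))
    simplices = remap[simplices]
    points = points[used]
    boundary = used < n_bnd
    normals = np.zeros((len(points), 2))
    normals[boundary] = boundary_nrm[used[boundary]]

    mesh = TriMesh(points=points, triangles=simplices, boundary=boundary,
                   boundary_normals=normals)
    if not boundary.any():
        raise MeshError("mesh has no boundary nodes")
    if (~boundary).sum() == 0:
        raise MeshError("mesh has no interior nodes; refine spacing")
    return mesh


def connected_component_count(mesh: TriMesh) -> int:
    """Number of edge-connected mesh components.

    Obstructed subarachnoid sections are often genuinely partitioned into
    several channels (roots and ligaments span cord to dura), so multiple
    components are legitimate: the solver treats them as parallel conduits
    sharing one axial pressure gradient.
    """
    from scipy.sparse.csgraph import connected_components

    t = mesh.triangles
    i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
    j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
    n = mesh.n_nodes
    adj = coo_matrix((np.ones_like(i), (i, j)), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    return int(ncomp)


def assemble_p1(mesh: TriMesh) -> tuple[csr_matrix, csr_matrix]:
    """Assemble P1 stiffness K and consistent mass M (units: mm-based).

    K_ij = int grad(phi_i).grad(phi_j) dA   (dimensionless in 2D)
    M_ij = int phi_i phi_j dA               (mm^2)
    """
    p = mesh.points
    t = mesh.triangles
    a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
    area = 0.5 * _cross2(b - a, c - a)
    if np.any(area <= 0):
        raise MeshError("non-positive triangle area in assembly")

    # gradients of barycentric basis functions
    g0 = np.stack([b[:, 1] - c[:, 1], c[:, 0] - b[:, 0]], axis=1)
    g1 = np.stack([c[:, 1] - a[:, 1], a[:, 0] - c[:, 0]], axis=1)
    g2 = np.stack([a[:, 1] - b[:, 1], b[:, 0] - a[:, 0]], axis=1)
    grads = np.stack([g0, g1, g2], axis=1) / (2.0 * area)[:, None, None]

    rows, cols, kv, mv = [], [], [], []
    mass_local = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            kv.append(area * np.einsum("nd,nd->n", grads[:, i], grads[:, j]))
            mv.append(area * mass_local[i, j])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    n = mesh.n_nodes
    K = coo_matrix((np.concatenate(kv), (rows, cols)), shape=(n, n)).tocsr()
    M = coo_matrix((np.concatenate(mv), (rows, cols)), shape=(n, n)).tocsr()
    return K, M
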
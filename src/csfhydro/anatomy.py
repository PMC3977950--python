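"""Parametric anatomy of the cervical spinal subarachnoid space (SSS).

The SSS is idealized as an eccentric annulus between the dura (outer
boundary) and the spinal cord (inner boundary).  Fine intradural
structures — the dorsal and ventral nerve roots and the denticulate
ligaments (collectively NRDL) — partially obstruct the annulus and are
inserted as planar footprints: nerve roots as stadium profiles whose long
axis extends radially from the cord, denticulate ligaments as thin
rectangles spanning cord to dura laterally between the root pairs.

Per-level root dimensions (radicular line length RL, median descending
angle theta, thickness t) ship as a CSV of cadaveric measurements; a plane
at a given level sees the projected in-plane chord ``RL * cos(theta)``
truncated to the dura-cord gap.

Coordinate conventions, used package-wide:

* axial axis = y, positive cranial; caudally directed flow has negative
  axial velocity;
* in-plane axes = (x, z) with dorsal = +z, ventral = -z, left = -x;
* angular positions are measured in degrees from the +x axis, CCW as seen
  looking in the -y (caudal) direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Point, Polygon

LEVELS = [f"C{i}" for i in range(1, 9)]
SIDES = ("left", "right")
KINDS = ("dorsal", "ventral")

#: The nine axial measurement planes, cranial to caudal.
STATIONS = ["FM", "C1", "C2M", "C2P", "C3", "C4", "C5", "C6", "C7"]

#: Root level whose structures intersect each station plane (None = clear).
STATION_LEVEL = {
    "FM": None, "C1": "C1", "C2M": "C2", "C2P": "C2",
    "C3": "C3", "C4": "C4", "C5": "C5", "C6": "C6", "C7": "C7",
}

#: Default ligament thickness bounds (mm): thin membranes, the smallest
#: value allowed by geometric constraints.
LIGAMENT_THICKNESS_BOUNDS = (0.1, 0.15)

#: Angular placement defaults (degrees from +x): dorsal roots toward +z,
#: ventral toward -z, ligaments lateral midway between the pairs.
ROOT_ANGLES = {
    ("left", "dorsal"): 125.0,
    ("right", "dorsal"): 55.0,
    ("left", "ventral"): 235.0,
    ("right", "ventral"): 305.0,
}
LIGAMENT_ANGLES = {"left": 180.0, "right": 0.0}

#: Boundary discretization for shapely curves (points per full circle).
CURVE_RESOLUTION = 512


class AnatomyError(ValueError):
    """Validation failure in anatomical specifications or geometry."""


@dataclass(frozen=True)
class NerveRootSpec:
    """One nerve root at one level/side: dorsal or ventral."""

    level: str
    side: str
    kind: str
    radicular_length: float      # RL, mm
    descending_angle: float      # theta, degrees; negative = caudal
    thickness: float             # t, mm
    scale: float = 1.0           # size scaling coefficient, (0, 1]

    def __post_init__(self):
        if self.level not in LEVELS:
            raise AnatomyError(f"unknown level {self.level!r}")
        if self.side not in SIDES:
            raise AnatomyError(f"unknown side {self.side!r}")
        if self.kind not in KINDS:
            raise AnatomyError(f"unknown kind {self.kind!r}")
        if not self.radicular_length > 0:
            raise AnatomyError(f"{self.level} {self.side} {self.kind}: "
                               f"radicular_length must be > 0")
        if not self.thickness > 0:
            raise AnatomyError(f"{self.level} {self.side} {self.kind}: "
                               f"thickness must be > 0")
        if not 0 < self.scale <= 1:
            raise AnatomyError("scale must lie in (0, 1]")

    @property
    def in_plane_extent(self) -> float:
        """Projected chord RL*cos(theta)*scale seen by an axial plane, mm."""
        return (self.scale * self.radicular_length
                * abs(math.cos(math.radians(self.descending_angle))))

    def scaled(self, scale: float) -> "NerveRootSpec":
        return replace(self, scale=scale,
                       radicular_length=self.radicular_length,
                       thickness=self.thickness)


@dataclass(frozen=True)
class LigamentSpec:
    """A denticulate ligament at one level/side: a thin cord-to-dura membrane."""

    level: str
    side: str = "left"
    thickness: float = 0.12      # mm
    span: float | None = None    # mm; None = full dura-cord gap
    placement: float | None = None  # degrees; None = lateral default
    thickness_bounds: tuple[float, float] = LIGAMENT_THICKNESS_BOUNDS

    def __post_init__(self):
        lo, hi = self.thickness_bounds
        if not lo <= self.thickness <= hi:
            raise AnatomyError(
                f"ligament thickness {self.thickness} mm outside the "
                f"configured bounds [{lo}, {hi}] mm")
        if self.span is not None and not self.span > 0:
            raise AnatomyError("ligament span must be > 0")
        if self.level not in LEVELS:
            raise AnatomyError(f"unknown level {self.level!r}")

    @property
    def angle(self) -> float:
        return LIGAMENT_ANGLES[self.side] if self.placement is None else self.placement


def _default_table_path():
    return resources.files("csfhydro.data") / "nrdl_table.csv"


def load_nrdl_table(source=None, scale: float = 1.0) -> list[NerveRootSpec]:
    """Load per-level nerve-root measurements into 32 specs.

    ``source`` is a CSV path with one row per (level, side) carrying dorsal
    and ventral RL/angle/thickness columns; the packaged cadaveric defaults
    are used when omitted.  Dorsal thickness is shared per level across
    sides (as measured).
    """
    path = _default_table_path() if source is None else Path(source)
    df = pd.read_csv(path)
    required = {"level", "side", "dorsal_RL_mm", "dorsal_theta_deg",
                "dorsal_thickness_mm", "ventral_RL_mm", "ventral_theta_deg",
                "ventral_thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise AnatomyError(f"nerve-root table missing columns: {sorted(missing)}")

    index = {(r.level, r.side): r for r in df.itertuples()}
    specs: list[NerveRootSpec] = []
    for level in LEVELS:
        for side in SIDES:
            if (level, side) not in index:
                raise AnatomyError(
                    f"nerve-root table has no row for level {level}, side {side}")
            row = index[(level, side)]
            for kind in KINDS:
                prefix = kind
                specs.append(NerveRootSpec(
                    level=level, side=side, kind=kind,
                    radicular_length=getattr(row, f"{prefix}_RL_mm"),
                    descending_angle=getattr(row, f"{prefix}_theta_deg"),
                    thickness=getattr(row, f"{prefix}_thickness_mm"),
                    scale=scale,
                ))
    return specs


def write_nrdl_table(specs: Iterable[NerveRootSpec], path) -> None:
    """Write specs back to the tabular CSV layout (inverse of load)."""
    rows = {}
    for s in specs:
        rows.setdefault((s.level, s.side), {})[s.kind] = s
    records = []
    for level in LEVELS:
        for side in SIDES:
            pair = rows.get((level, side))
            if pair is None or set(pair) != set(KINDS):
                raise AnatomyError(f"incomplete spec set at {level} {side}")
            d, v = pair["dorsal"], pair["ventral"]
            records.append(dict(
                level=level, side=side,
                dorsal_RL_mm=d.radicular_length,
                dorsal_theta_deg=d.descending_angle,
                dorsal_thickness_mm=d.thickness,
                ventral_RL_mm=v.radicular_length,
                ventral_theta_deg=v.descending_angle,
                ventral_thickness_mm=v.thickness,
            ))
    pd.DataFrame.from_records(records).to_csv(path, index=False)


@dataclass(frozen=True)
class StationParams:
    """Idealized dura/cord geometry of one axial plane."""

    station: str
    dura_radius: float           # mm
    cord_radius: float           # mm
    eccentricity: float = 0.0    # mm, cord-center offset along +z (dorsal)

    def __post_init__(self):
        if not self.dura_radius > self.cord_radius > 0:
            raise AnatomyError(
                f"{self.station}: need dura_radius > cord_radius > 0")
        if abs(self.eccentricity) + self.cord_radius >= self.dura_radius:
            raise AnatomyError(f"{self.station}: cord escapes the dura")

    @property
    def gap(self) -> float:
        """Minimum dura-cord gap, mm."""
        return self.dura_radius - self.cord_radius - abs(self.eccentricity)


def _circle(center, radius) -> Polygon:
    return Point(center).buffer(radius, quad_segs=CURVE_RESOLUTION // 4)


@dataclass
class CrossSection:
    """A multiply-connected SSS slice with derived geometric metrics."""

    station: str
    params: StationParams
    lumen: Polygon | MultiPolygon
    obstructions: list = field(default_factory=list)
    rootlet_ridges: list = field(default_factory=list)  # metadata for 3D export

    @property
    def area(self) -> float:
        """Cross-sectional area A_c, mm^2."""
        return float(self.lumen.area)

    @property
    def wetted_perimeter(self) -> float:
        """Total wetted boundary length P (dura + cord + obstructions), mm."""
        total = 0.0
        for part in (self.lumen.geoms if isinstance(self.lumen, MultiPolygon)
                     else [self.lumen]):
            total += part.exterior.length
            total += sum(r.length for r in part.interiors)
        return float(total)

    @property
    def hydraulic_diameter(self) -> float:
        """D_h = 4 A_c / P, mm."""
        return 4.0 * self.area / self.wetted_perimeter


def geometric_metrics(section: CrossSection) -> tuple[float, float, float]:
    """Return (A_c mm^2, wetted perimeter P mm, hydraulic diameter D_h mm)."""
    if section.lumen.is_empty or section.area <= 0:
        raise AnatomyError(f"{section.station}: degenerate (zero-area) section")
    return section.area, section.wetted_perimeter, section.hydraulic_diameter


def _root_footprint(params: StationParams, root: NerveRootSpec) -> Polygon:
    """Stadium profile: radial segment from the cord surface, buffered by t/2."""
    ang = math.radians(ROOT_ANGLES[(root.side, root.kind)])
    direction = np.array([math.cos(ang), math.sin(ang)])
    start = np.array([0.0, params.eccentricity]) + params.cord_radius * direction
    # extend from just inside the cord so the footprint merges with the cord
    # hole rather than leaving a sliver channel
    tail = start - 0.2 * direction
    length = root.in_plane_extent
    tip = start + length * direction
    seg = LineString([tail, tip])
    return seg.buffer(root.thickness / 2.0, quad_segs=16)


def _ligament_footprint(params: StationParams, lig: LigamentSpec) -> Polygon:
    ang = math.radians(lig.angle)
    direction = np.array([math.cos(ang), math.sin(ang)])
    start = np.array([0.0, params.eccentricity]) + params.cord_radius * direction
    tail = start - 0.2 * direction
    span = lig.span if lig.span is not None else 2.0 * params.dura_radius
    tip = start + span * direction
    seg = LineString([tail, tip])
    return seg.buffer(lig.thickness / 2.0, quad_segs=8, cap_style="flat")


def build_cross_section(
    params: StationParams,
    roots: Sequence[NerveRootSpec] = (),
    ligaments: Sequence[LigamentSpec] = (),
) -> CrossSection:
    """Assemble one axial SSS slice with NRDL obstruction footprints.

    Root and ligament footprints are truncated to the annular lumen; an
    obstruction whose footprint misses the lumen entirely, or dorsal and
    ventral footprints that overlap each other, raise :class:`AnatomyError`.
    """
    dura = _circle((0.0, 0.0), params.dura_radius)
    cord = _circle((0.0, params.eccentricity), params.cord_radius)
    annulus = dura.difference(cord)

    footprints = []
    labels = []
    for root in roots:
        raw = _root_footprint(params, root)
        clipped = raw.intersection(annulus)
        if clipped.is_empty or clipped.area <= 0:
            raise AnatomyError(
                f"{params.station}: {root.level} {root.side} {root.kind} "
                f"root footprint escapes the lumen")
        footprints.append(clipped)
        labels.append(("root", root))
    n_roots = len(footprints)
    for i in range(n_roots):
        for j in range(i + 1, n_roots):
            ri, rj = labels[i][1], labels[j][1]
            if ri.side == rj.side and ri.kind != rj.kind \
                    and footprints[i].intersects(footprints[j]):
                raise AnatomyError(
                    f"{params.station}: dorsal and ventral footprints overlap "
                    f"on the {ri.side} side")
    for lig in ligaments:
        raw = _ligament_footprint(params, lig)
        clipped = raw.intersection(annulus)
        if clipped.is_empty or clipped.area <= 0:
            raise AnatomyError(
                f"{params.station}: ligament {lig.level} {lig.side} footprint "
                f"escapes the lumen")
        footprints.append(clipped)
        labels.append(("ligament", lig))

    lumen = annulus
    for fp in footprints:
        lumen = lumen.difference(fp)
    if lumen.is_empty or lumen.area <= 0:
        raise AnatomyError(f"{params.station}: obstructions obliterate the lumen")

    ridges = [spec for kind, spec in labels
              if kind == "root" and spec.kind == "dorsal"]
    return CrossSection(
        station=params.station, params=params, lumen=lumen,
        obstructions=footprints, rootlet_ridges=ridges,
    )


# ---------------------------------------------------------------------------
# Whole-model geometry


#: Default per-station dura/cord radii (mm).  Outer radii are set so that the
#: plain concentric-annulus areas match areas reported for an adult cervical
#: SSS without fine structures; cord radii taper over literature-typical
#: cervical values.
DEFAULT_STATION_RADII = {
    # station: (dura_radius, cord_radius)
    "FM":  (14.674, 4.6),
    "C1":  (11.236, 4.5),
    "C2M": (9.753, 4.4),
    "C2P": (9.116, 4.3),
    "C3":  (8.223, 4.2),
    "C4":  (8.035, 4.1),
    "C5":  (7.884, 4.0),
    "C6":  (8.162, 4.0),
    "C7":  (8.093, 3.9),
}

#: Default axial station spacing (mm): equal spacing over the cervical span.
DEFAULT_STATION_SPACING = 17.5


@dataclass
class GeometryModel:
    """Ordered stations with cross-sections and contiguous axial segments."""

    sections: dict                      # station -> CrossSection
    axial_positions: dict               # station -> y (mm, positive cranial)
    with_nrdl: bool
    scale: float = 1.0

    @property
    def stations(self) -> list[str]:
        return list(STATIONS)

    @property
    def segments(self) -> list[tuple[str, str]]:
        return list(zip(STATIONS[:-1], STATIONS[1:]))

    def segment_length(self, segment: tuple[str, str]) -> float:
        up, dn = segment
        return abs(self.axial_positions[up] - self.axial_positions[dn])

    def metrics_table(self) -> pd.DataFrame:
        rows = []
        for st in self.stations:
            a, p, dh = geometric_metrics(self.sections[st])
            rows.append(dict(station=st, y_mm=self.axial_positions[st],
                             A_c_mm2=a, P_mm=p, D_h_mm=dh,
                             n_obstructions=len(self.sections[st].obstructions)))
        return pd.DataFrame(rows)


def build_geometry(
    with_nrdl: bool = True,
    scale: float = 1.0,
    station_radii: dict | None = None,
    eccentricity: float = 0.0,
    spacing: float = DEFAULT_STATION_SPACING,
    nrdl_source=None,
    ligament_thickness: float = 0.12,
    active_levels: Sequence[str] | None = None,
) -> GeometryModel:
    """Build the nine-station cervical model, with or without NRDL.

    Station plane at level L carries the roots and ligaments of level L
    (the two C2 planes share the C2 structures); the foramen magnum plane
    is always clear, the first roots appearing at C1.
    """
    radii = dict(DEFAULT_STATION_RADII)
    if station_radii:
        radii.update(station_radii)
    specs = load_nrdl_table(nrdl_source, scale=scale) if with_nrdl else []
    by_level: dict[str, list[NerveRootSpec]] = {}
    for s in specs:
        by_level.setdefault(s.level, []).append(s)

    sections = {}
    positions = {}
    for i, st in enumerate(STATIONS):
        ro, ri = radii[st]
        params = StationParams(station=st, dura_radius=ro, cord_radius=ri,
                               eccentricity=eccentricity)
        level = STATION_LEVEL[st]
        active = (active_levels is None or (level in active_levels))
        if with_nrdl and level is not None and active:
            roots = by_level[level]
            ligaments = [LigamentSpec(level=level, side=s,
                                      thickness=ligament_thickness)
                         for s in SIDES]
        else:
            roots, ligaments = [], []
        sections[st] = build_cross_section(params, roots, ligaments)
        positions[st] = spacing * (len(STATIONS) - 1 - i)

    return GeometryModel(sections=sections, axial_positions=positions,
                         with_nrdl=with_nrdl, scale=scale)
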
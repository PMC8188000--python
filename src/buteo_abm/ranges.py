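"""Percentage-polygon home-range metrics, overlaps, abundance, occupancy.

The home-range core at level *x* is the convex hull of the ``ceil(x% * n)``
locations nearest the arithmetic-mean centre of all *n* locations (the
classic peeled convex-polygon estimator, single ranking from a fixed
centre).  For a virtual bird the location set is its territory pixel
centres.  Cores above 85% are excluded from defaults because such outlines
tend to capture non-foraging excursions; the standard profile runs from 30%
to 80% at 5% steps (11 levels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, MultiPoint, Polygon
from shapely.geometry.base import BaseGeometry

from buteo_abm.engine import Buzzard, SimulationResult, _FREE
from buteo_abm.landscape import InvalidInputError, StudyMask

log = logging.getLogger(__name__)

#: Default core levels: 30-80% at 5% steps (11 levels).
DEFAULT_LEVELS: tuple[int, ...] = tuple(range(30, 85, 5))

#: Levels above this tend to include non-foraging excursions; excluded by default.
MAX_DEFAULT_LEVEL = 85


@dataclass
class RangeCore:
    """A percentage convex polygon of one bird at one core level."""

    bird_id: int
    level: float
    polygon: BaseGeometry
    area_ha: float
    perimeter_m: float


@dataclass
class OverlapRecord:
    """Directed overlap of two cores: intersection as % of the first core's area."""

    bird_a: int
    bird_b: int
    level: float
    overlap_pct: float


def _hull_metrics(geom: BaseGeometry) -> tuple[float, float]:
    """(area_ha, perimeter_m) of a hull; degenerate hulls have zero area and
    perimeter equal to the out-and-back traversal of the figure."""
    if isinstance(geom, Polygon):
        return geom.area / 10_000.0, geom.exterior.length
    if isinstance(geom, LineString):
        return 0.0, 2.0 * geom.length
    return 0.0, 0.0  # Point


def percentage_polygon(
    points: np.ndarray, level: float, bird_id: int = -1
) -> RangeCore:
    """Convex hull of the ``ceil(level% * n)`` points nearest the mean centre.

    A single distance ranking from the fixed arithmetic-mean centre of all
    points; ties broken by input order (stable sort).  Degenerate retained
    sets (one point, two points, collinear) yield zero-area geometry with a
    defined perimeter.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        raise InvalidInputError("percentage_polygon needs at least one point")
    if not 0 < level <= 100:
        raise InvalidInputError(f"level must be in (0, 100], got {level}")
    centre = pts.mean(axis=0)
    dist = np.hypot(pts[:, 0] - centre[0], pts[:, 1] - centre[1])
    keep = int(np.ceil(level / 100.0 * pts.shape[0]))
    order = np.argsort(dist, kind="stable")[:keep]
    hull = MultiPoint(pts[order]).convex_hull
    area_ha, perimeter = _hull_metrics(hull)
    return RangeCore(bird_id=bird_id, level=float(level), polygon=hull,
                     area_ha=area_ha, perimeter_m=perimeter)


def core_profile(
    bird: Buzzard, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> list[RangeCore]:
    """Range cores of one bird at each level, over its territory pixel centres."""
    pts = bird.locations()
    return [percentage_polygon(pts, lv, bird_id=bird.name) for lv in levels]


def pairwise_overlaps(
    cores: list[RangeCore], symmetric: bool = False
) -> list[OverlapRecord]:
    """Overlap records for every pair of cores with positive intersection area.

    Directed by default: ``(A, B)`` reports the intersection as a percentage
    of A's core area, and ``(B, A)`` of B's.  With ``symmetric=True`` a
    single record per pair reports intersection over union.  Cores must all
    be at the same level; zero-area cores are skipped with a log message.
    """
    levels = {c.level for c in cores}
    if len(levels) > 1:
        raise InvalidInputError(f"cores span multiple levels: {sorted(levels)}")
    records: list[OverlapRecord] = []
    for i, a in enumerate(cores):
        for b in cores[i + 1 :]:
            if a.area_ha == 0 or b.area_ha == 0:
                log.debug("skipping overlap of zero-area core pair (%s, %s)", a.bird_id, b.bird_id)
                continue
            inter = a.polygon.intersection(b.polygon).area
            if inter <= 0:
                continue
            if symmetric:
                union = a.polygon.union(b.polygon).area
                records.append(OverlapRecord(a.bird_id, b.bird_id, a.level, 100.0 * inter / union))
            else:
                records.append(OverlapRecord(a.bird_id, b.bird_id, a.level,
                                             100.0 * inter / (a.area_ha * 10_000.0)))
                records.append(OverlapRecord(b.bird_id, a.bird_id, a.level,
                                             100.0 * inter / (b.area_ha * 10_000.0)))
    return records


def abundance(result: SimulationResult, mask: StudyMask) -> int:
    """Number of settled birds whose roost pixel lies in the core study area.

    Birds roosting in the boundary strip still block pixels (their
    territories are simulated) but do not count toward abundance.
    """
    if mask.core.shape != result.state.resource.shape:
        raise InvalidInputError("mask and result grids disagree")
    return sum(1 for b in result.buzzards if mask.core[b.my_roost[1], b.my_roost[0]])


@dataclass
class OccupancyRaster:
    """Owner ID per pixel (-1 = background) with roost pixels flagged."""

    owners: np.ndarray
    roosts: np.ndarray


def occupancy_raster(result: SimulationResult) -> OccupancyRaster:
    """Territory raster: per-pixel owner IDs, roost pixels flagged distinctly."""
    owners = np.full(result.state.resource.shape, _FREE, dtype=np.int32)
    roosts = np.zeros(result.state.resource.shape, dtype=bool)
    for bird in result.buzzards:
        for c, r in bird.territory_pixels:
            owners[r, c] = bird.name
        roosts[bird.my_roost[1], bird.my_roost[0]] = True
    return OccupancyRaster(owners=owners, roosts=roosts)


def mean_core_profile(
    birds: list[Buzzard], levels: tuple[float, ...] = DEFAULT_LEVELS
) -> np.ndarray:
    """Mean core area (ha) per level pooled over birds; NaN when no birds."""
    if not birds:
        return np.full(len(levels), np.nan)
    areas = np.array([[c.area_ha for c in core_profile(b, levels)] for b in birds])
    return areas.mean(axis=0)
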
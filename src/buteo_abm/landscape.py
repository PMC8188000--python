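"""Categorical resource rasters: translation, patch labelling, study masks.

A :class:`ResourceMap` is a square-pixel categorical raster holding one
resource code per pixel.  The five codes cover everything a buzzard cares
about: woodland (roosting), rough-ground and meadow (hunting), "other"
(non-resource land) and water (never claimable, also used for NODATA).

Conventions used throughout the package:

* the grid is stored row-major with row 0 at the *northern* edge, as in
  every common raster format;
* pixel indices are ``(col, row)``, 0-based;
* geographic positions are pixel centres, in metres of the map's planar
  coordinate system (eastings/northings);
* distances are Euclidean, centre to centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage


class Resource(IntEnum):
    """Resource category of a pixel in the buzzard resource map."""

    OTHER = 0
    WOODLAND = 1
    ROUGH = 2
    MEADOW = 3
    WATER = 4


#: Canonical text names, used in mapping tables and CLI output.
RESOURCE_NAMES: dict[Resource, str] = {
    Resource.OTHER: "other",
    Resource.WOODLAND: "woodland",
    Resource.ROUGH: "rough-ground",
    Resource.MEADOW: "meadow",
    Resource.WATER: "water",
}

_NAME_TO_RESOURCE = {name: res for res, name in RESOURCE_NAMES.items()}
_NAME_TO_RESOURCE["rough_ground"] = Resource.ROUGH
_NAME_TO_RESOURCE["rough"] = Resource.ROUGH


def resource_from_name(name: str) -> Resource:
    try:
        return _NAME_TO_RESOURCE[name.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown resource name: {name!r}") from None


class InvalidInputError(ValueError):
    """Raised when an operation's input violates its contract."""


class UnsupportedFormatError(ValueError):
    """Raised for raster files the package cannot represent (e.g. non-square pixels)."""


@dataclass
class ResourceMap:
    """Square-pixel categorical raster of buzzard resources.

    Parameters
    ----------
    grid
        2-D integer array of :class:`Resource` codes, shape ``(n_rows, n_cols)``,
        row 0 at the northern edge.
    pixel_size
        Side of a (square) pixel in metres.
    origin
        ``(easting, northing)`` of the grid's lower-left *corner*, metres.
    crs_epsg
        Optional EPSG code of the planar CRS (e.g. 27700 for the British
        National Grid); carried through I/O, never used in computation.
    """

    grid: np.ndarray
    pixel_size: float = 25.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_epsg: int | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.size == 0:
            raise InvalidInputError("resource grid must be a non-empty 2-D array")
        if not self.pixel_size > 0:
            raise InvalidInputError("pixel_size must be positive")
        valid = np.isin(self.grid, [int(r) for r in Resource])
        if not valid.all():
            bad = np.unique(self.grid[~valid])
            raise InvalidInputError(f"grid holds invalid resource codes: {bad.tolist()}")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def map_eastings(self) -> float:
        """E-W extent in metres."""
        return self.n_cols * self.pixel_size

    @property
    def map_northings(self) -> float:
        """N-S extent in metres."""
        return self.n_rows * self.pixel_size

    @property
    def pixel_area_ha(self) -> float:
        """Area of one pixel in hectares: (pixel_size/100)**2, 0.0625 ha at 25 m."""
        return (self.pixel_size / 100.0) ** 2

    def pixel_centre(self, col: int, row: int) -> tuple[float, float]:
        """Easting/northing of the centre of pixel ``(col, row)``."""
        x = self.origin[0] + (col + 0.5) * self.pixel_size
        y = self.origin[1] + (self.n_rows - row - 0.5) * self.pixel_size
        return x, y

    def centres(self, pixels: Iterable[tuple[int, int]]) -> np.ndarray:
        """Centres of many ``(col, row)`` pixels as an ``(n, 2)`` array."""
        arr = np.asarray(list(pixels), dtype=float)
        if arr.size == 0:
            return arr.reshape(0, 2)
        x = self.origin[0] + (arr[:, 0] + 0.5) * self.pixel_size
        y = self.origin[1] + (self.n_rows - arr[:, 1] - 0.5) * self.pixel_size
        return np.column_stack([x, y])

    def counts(self) -> dict[Resource, int]:
        """Pixel count per resource code."""
        return {res: int(np.count_nonzero(self.grid == int(res))) for res in Resource}

    def copy(self) -> "ResourceMap":
        return ResourceMap(self.grid.copy(), self.pixel_size, self.origin, self.crs_epsg)


@dataclass
class CategoryMapping:
    """Total mapping from land-cover category IDs to resource codes.

    IDs absent from ``entries`` resolve to :attr:`Resource.OTHER`, so the
    mapping is total after the default.
    """

    entries: dict[int, Resource] = field(default_factory=dict)

    def __getitem__(self, map_cat: int) -> Resource:
        return self.entries.get(int(map_cat), Resource.OTHER)

    @classmethod
    def from_table(cls, path: str | Path) -> "CategoryMapping":
        """Read a 2-column delimited table ``map_cat, resource`` (CSV/TSV)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        if df.shape[1] < 2:
            raise InvalidInputError("mapping table needs columns: map_cat, resource")
        ids = df.iloc[:, 0].astype(int)
        names = df.iloc[:, 1].astype(str)
        return cls({int(i): resource_from_name(n) for i, n in zip(ids, names)})

    def to_table(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "map_cat": list(self.entries),
                "resource": [RESOURCE_NAMES[r] for r in self.entries.values()],
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class Patch:
    """One connected patch of a single resource."""

    resource: Resource
    pixels: frozenset[tuple[int, int]]
    area_ha: float

    def __len__(self) -> int:
        return len(self.pixels)


@dataclass
class StudyMask:
    """Boolean core study area plus the width of the surrounding boundary strip.

    Pixels outside ``core`` but inside the world are the boundary strip: they
    are simulated (birds may roost and defend there) but excluded from
    abundance and distribution predictions.
    """

    core: np.ndarray
    strip_width: float = 0.0

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=bool)


def translate_landcover(
    landcover: np.ndarray,
    mapping: CategoryMapping,
    pixel_size: float = 25.0,
    origin: tuple[float, float] = (0.0, 0.0),
    crs_epsg: int | None = None,
) -> ResourceMap:
    """Translate a land-cover category raster into a buzzard resource map.

    Every pixel's integer category ID is looked up in ``mapping``; unmapped
    IDs become "other".  Pixel counts per resource equal the counts of source
    IDs per mapping class.
    """
    landcover = np.asarray(landcover)
    if landcover.ndim != 2 or landcover.size == 0:
        raise InvalidInputError("land-cover grid must be a non-empty 2-D array")
    out = np.full(landcover.shape, int(Resource.OTHER), dtype=np.int8)
    for cat, res in mapping.entries.items():
        out[landcover == cat] = int(res)
    return ResourceMap(out, pixel_size=pixel_size, origin=origin, crs_epsg=crs_epsg)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise InvalidInputError(f"connectivity must be 4 or 8, got {connectivity}")


def label_patches(
    rmap: ResourceMap, resource: Resource, connectivity: int = 8
) -> list[Patch]:
    """Partition all pixels of one resource into connected patches.

    Diagonal adjacency counts under the default 8-connectivity, matching the
    flood-fill rule of the settlement engine.
    """
    resource = Resource(resource)
    mask = rmap.grid == int(resource)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    patches: list[Patch] = []
    if n == 0:
        return patches
    rows, cols = np.nonzero(labels)
    labs = labels[rows, cols]
    order = np.argsort(labs, kind="stable")
    rows, cols, labs = rows[order], cols[order], labs[order]
    bounds = np.searchsorted(labs, np.arange(1, n + 2))
    for k in range(n):
        lo, hi = bounds[k], bounds[k + 1]
        px = frozenset(zip(cols[lo:hi].tolist(), rows[lo:hi].tolist()))
        patches.append(Patch(resource, px, len(px) * rmap.pixel_area_ha))
    return patches


def make_study_mask(
    rmap: ResourceMap,
    core_extent: tuple[float, float, float, float],
    strip_width: float,
) -> StudyMask:
    """Build the core study-area mask inside the simulated world.

    ``core_extent`` is ``(xmin, ymin, xmax, ymax)`` in metres.  A pixel is in
    the core iff its centre falls in the rectangle.  The strip between the
    core and the world edge is recorded by its nominal width only.
    """
    xmin, ymin, xmax, ymax = core_extent
    wx0, wy0 = rmap.origin
    wx1 = wx0 + rmap.map_eastings
    wy1 = wy0 + rmap.map_northings
    if xmin < wx0 or ymin < wy0 or xmax > wx1 or ymax > wy1 or xmin >= xmax or ymin >= ymax:
        raise InvalidInputError("core_extent must be a non-empty rectangle within the world")
    cols = np.arange(rmap.n_cols)
    rows = np.arange(rmap.n_rows)
    cx = wx0 + (cols + 0.5) * rmap.pixel_size
    cy = wy0 + (rmap.n_rows - rows - 0.5) * rmap.pixel_size
    in_x = (cx >= xmin) & (cx <= xmax)
    in_y = (cy >= ymin) & (cy <= ymax)
    core = np.outer(in_y, in_x)
    return StudyMask(core=core, strip_width=float(strip_width))


def full_mask(rmap: ResourceMap) -> StudyMask:
    """Mask whose core is the whole world (no boundary strip)."""
    return StudyMask(core=np.ones(rmap.grid.shape, dtype=bool), strip_width=0.0)
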
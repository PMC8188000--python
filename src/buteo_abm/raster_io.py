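"""Reading and writing resource maps as GeoTIFF or ESRI ASCII grids.

GeoTIFF support is single-band integer with the three tags that matter for a
square-pixel planar raster: ModelPixelScale, ModelTiepoint and a minimal
GeoKeyDirectory carrying the projected EPSG code.  ESRI ASCII grids follow
the standard 6-line header; NODATA cells are mapped to the "water" code on
read, and water is written back as NODATA (water is never claimable, so the
round trip is information-preserving for the model).

Non-square pixels are refused: the model's hectare arithmetic assumes them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from buteo_abm.landscape import (
    InvalidInputError,
    Resource,
    ResourceMap,
    UnsupportedFormatError,
)

_ASCII_NODATA = -9999

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_PROJECTED_CS_TYPE_GEOKEY = 3072


def write_ascii_grid(rmap: ResourceMap, path: str | Path) -> None:
    grid = rmap.grid.astype(int).copy()
    grid[grid == int(Resource.WATER)] = _ASCII_NODATA
    header = (
        f"ncols {rmap.n_cols}\n"
        f"nrows {rmap.n_rows}\n"
        f"xllcorner {rmap.origin[0]:.6f}\n"
        f"yllcorner {rmap.origin[1]:.6f}\n"
        f"cellsize {rmap.pixel_size:.6f}\n"
        f"NODATA_value {_ASCII_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt="%d")


def read_ascii_grid(path: str | Path) -> ResourceMap:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2 or not line[0][0].isalpha():
                break
            header[line[0].lower()] = float(line[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise UnsupportedFormatError(f"ASCII grid missing header field {key}")
    if "dx" in header or "dy" in header:
        raise UnsupportedFormatError("non-square pixels (dx/dy headers) are not supported")
    nodata = header.get("nodata_value", _ASCII_NODATA)
    grid = data.astype(int)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InvalidInputError("ASCII grid data shape disagrees with header")
    grid[grid == int(nodata)] = int(Resource.WATER)
    known = np.isin(grid, [int(r) for r in Resource])
    if not known.all():
        bad = np.unique(grid[~known])
        raise InvalidInputError(f"unknown resource codes in {path}: {bad.tolist()}")
    return ResourceMap(
        grid.astype(np.int8),
        pixel_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def write_geotiff(rmap: ResourceMap, path: str | Path) -> None:
    px = float(rmap.pixel_size)
    top_y = rmap.origin[1] + rmap.map_northings
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (px, px, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(rmap.origin[0]), float(top_y), 0.0)),
    ]
    if rmap.crs_epsg is not None:
        # Minimal GeoKeyDirectory: version 1.1.0, one key (ProjectedCSType).
        keys = (1, 1, 0, 1, _PROJECTED_CS_TYPE_GEOKEY, 0, 1, int(rmap.crs_epsg))
        extratags.append((_GEO_KEY_DIRECTORY, "H", len(keys), keys))
    tifffile.imwrite(path, rmap.grid.astype(np.uint8), extratags=extratags)


def read_geotiff(path: str | Path) -> ResourceMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        grid = page.asarray()
        tags = page.tags
        scale = tags[_MODEL_PIXEL_SCALE].value if _MODEL_PIXEL_SCALE in tags else None
        tiepoint = tags[_MODEL_TIEPOINT].value if _MODEL_TIEPOINT in tags else None
        geokeys = tags[_GEO_KEY_DIRECTORY].value if _GEO_KEY_DIRECTORY in tags else None
    if grid.ndim != 2:
        raise UnsupportedFormatError("only single-band rasters are supported")
    pixel_size, origin = 25.0, (0.0, 0.0)
    if scale is not None:
        sx, sy = float(scale[0]), float(scale[1])
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise UnsupportedFormatError(f"non-square pixels: {sx} x {sy} m")
        pixel_size = sx
    if tiepoint is not None:
        _, _, _, x0, top_y, _ = (float(v) for v in tiepoint[:6])
        origin = (x0, top_y - grid.shape[0] * pixel_size)
    epsg = None
    if geokeys is not None:
        vals = list(geokeys)
        for k in range(4, len(vals) - 3, 4):
            if vals[k] == _PROJECTED_CS_TYPE_GEOKEY:
                epsg = int(vals[k + 3])
    grid = grid.astype(int)
    known = np.isin(grid, [int(r) for r in Resource])
    if not known.all():
        bad = np.unique(grid[~known])
        raise InvalidInputError(f"unknown resource codes in {path}: {bad.tolist()}")
    return ResourceMap(grid.astype(np.int8), pixel_size=pixel_size, origin=origin, crs_epsg=epsg)


def write_resource_map(rmap: ResourceMap, path: str | Path) -> None:
    """Write a resource map; format chosen by extension (.tif/.tiff or .asc/.txt)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        write_geotiff(rmap, path)
    elif suffix in (".asc", ".txt", ".grd"):
        write_ascii_grid(rmap, path)
    else:
        raise UnsupportedFormatError(f"unsupported raster extension: {suffix!r}")


def read_resource_map(path: str | Path) -> ResourceMap:
    """Read a resource map; format chosen by extension (.tif/.tiff or .asc/.txt)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path)
    if suffix in (".asc", ".txt", ".grd"):
        return read_ascii_grid(path)
    raise UnsupportedFormatError(f"unsupported raster extension: {suffix!r}")
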
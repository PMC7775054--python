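"""Minimal GeoTIFF I/O for north-up regular grids, built on tifffile.

Writes standard GeoTIFF georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory for geographic WGS84, and the GDAL nodata
tag) plus a JSON ImageDescription carrying band labels and free-form
metadata. Multi-band rasters are stored one band per page. Only the
conventions this package emits are supported: north-up grids, cell-area
registration, a single CRS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922
_GEOTIFF_KEYDIRECTORY = 34735
_GDAL_NODATA = 42113

# GTModelType=Geographic, RasterType=PixelIsArea, GeographicType=WGS84
_WGS84_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)


@dataclass(frozen=True)
class GridGeometry:
    """North-up regular grid: origin at the north-west corner.

    ``x0``/``y0`` are the west and north edges; ``dx``/``dy`` are positive
    cell sizes. Row 0 is the northernmost row. Cell centers sit at
    ``x0 + (col + 0.5) dx`` and ``y0 - (row + 0.5) dy``.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    crs: str = "EPSG:4326"
    nodata: float = -9999.0

    def extent(self, n_rows: int, n_cols: int):
        """(xmin, ymin, xmax, ymax) of the full grid."""
        return (self.x0, self.y0 - n_rows * self.dy,
                self.x0 + n_cols * self.dx, self.y0)

    def window(self, extent, n_rows: int, n_cols: int):
        """Row/col slice covering a geographic extent, clipped to the grid."""
        xmin, ymin, xmax, ymax = extent
        c0 = max(0, int(np.floor((xmin - self.x0) / self.dx)))
        c1 = min(n_cols, int(np.ceil((xmax - self.x0) / self.dx)))
        r0 = max(0, int(np.floor((self.y0 - ymax) / self.dy)))
        r1 = min(n_rows, int(np.ceil((self.y0 - ymin) / self.dy)))
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"extent {extent} does not intersect the grid")
        return r0, r1, c0, c1

    def sub(self, r0: int, c0: int) -> "GridGeometry":
        """Geometry of a sub-grid whose (0, 0) cell is this grid's (r0, c0)."""
        return replace(self, x0=self.x0 + c0 * self.dx, y0=self.y0 - r0 * self.dy)


def write_geotiff(path, data, geometry: GridGeometry, band_labels=None,
                  nodata=None, meta=None, dtype=None) -> Path:
    """Write a (bands, rows, cols) or (rows, cols) array as a GeoTIFF.

    ``band_labels`` (e.g. ISO dates) and ``meta`` are stored in a JSON
    ImageDescription. NaNs in float data are replaced by ``nodata``
    (default: the geometry's nodata code).
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("data must be 2-D or 3-D (bands, rows, cols)")
    if dtype is not None:
        arr = arr.astype(dtype)
    if nodata is None:
        nodata = geometry.nodata
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.where(np.isnan(arr), nodata, arr).astype(arr.dtype)

    if band_labels is not None and len(band_labels) != arr.shape[0]:
        raise ValueError("band_labels length must equal the band count")
    desc = {
        "bands": [str(b) for b in band_labels] if band_labels is not None else None,
        "crs": geometry.crs,
        "nodata": float(nodata),
        "meta": meta or {},
    }
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (geometry.dx, geometry.dy, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, geometry.x0, geometry.y0, 0.0)),
        (_GEOTIFF_KEYDIRECTORY, "H", len(_WGS84_KEYS), _WGS84_KEYS),
        (_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        path, arr, photometric="minisblack",
        description=json.dumps(desc, sort_keys=True),
        extratags=extratags,
    )
    return path


def read_geotiff(path):
    """Read a GeoTIFF written by :func:`write_geotiff`.

    Returns ``(array, geometry, band_labels, meta)`` with the array always
    (bands, rows, cols); nodata values in float data are returned as NaN.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        tags = page.tags
        scale = tags[_GEOTIFF_PIXELSCALE].value
        tie = tags[_GEOTIFF_TIEPOINT].value
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except (json.JSONDecodeError, TypeError):
                desc = {}
        nodata = desc.get("nodata")
        if nodata is None and _GDAL_NODATA in tags:
            nodata = float(tags[_GDAL_NODATA].value)
    if arr.ndim == 2:
        arr = arr[None, ...]
    geometry = GridGeometry(
        x0=float(tie[3]), y0=float(tie[4]), dx=float(scale[0]), dy=float(scale[1]),
        crs=desc.get("crs", "EPSG:4326"),
        nodata=float(nodata) if nodata is not None else -9999.0,
    )
    if np.issubdtype(arr.dtype, np.floating) and nodata is not None:
        arr = np.where(arr == float(nodata), np.nan, arr)
    return arr, geometry, desc.get("bands"), desc.get("meta", {})
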
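"""Minimal georeferenced raster container and GeoTIFF I/O.

Rasters are numpy arrays plus an affine transform, a CRS tag and a
nodata value.  GeoTIFFs are written through ``tifffile`` with the
standard georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory carrying the EPSG code, and GDAL's nodata tag), which is
sufficient for north-up imagery and round-trips through GIS software.
Rotated/sheared transforms are not supported.

The CRS is carried as an ``"EPSG:nnnn"`` string.  Whether a CRS is
geographic (degree units) is decided by EPSG number range — 4326 and the
4000–4999 block are geographic coordinate systems — which covers the
codes this toolchain encounters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np
import tifffile

__all__ = ["Affine", "Raster", "read_geotiff", "write_geotiff", "is_geographic"]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_KEY_GT_MODEL_TYPE = 1024
_KEY_GT_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


class Affine(NamedTuple):
    """Row-major 2x3 affine: x = a*col + b*row + c; y = d*col + e*row + f."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float,
                    xsize: float, ysize: float) -> "Affine":
        """North-up transform from the upper-left corner and pixel sizes
        (``ysize`` positive; rows increase southwards)."""
        return cls(xsize, 0.0, west, 0.0, -ysize, north)

    def xy(self, row, col, offset: float = 0.5):
        """Map pixel indices to CRS coordinates (default: pixel centers)."""
        col = np.asarray(col, dtype=np.float64) + offset
        row = np.asarray(row, dtype=np.float64) + offset
        return self.a * col + self.b * row + self.c, \
            self.d * col + self.e * row + self.f

    def rowcol(self, x, y):
        """Inverse map: CRS coordinates to (row, col) float indices."""
        x = np.asarray(x, dtype=np.float64) - self.c
        y = np.asarray(y, dtype=np.float64) - self.f
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("singular affine transform")
        col = (self.e * x - self.b * y) / det
        row = (self.a * y - self.d * x) / det
        return row, col

    @property
    def is_rectilinear(self) -> bool:
        return self.b == 0.0 and self.d == 0.0


def is_geographic(crs: str | None) -> bool:
    """Heuristic: EPSG codes 4326 / 4000–4999 are geographic (degrees)."""
    if crs is None:
        return False
    code = int(str(crs).upper().replace("EPSG:", ""))
    return 4000 <= code < 5000


@dataclass
class Raster:
    """A raster band stack with georeferencing.

    ``data`` is (rows, cols) for a single band or (rows, cols, bands) for
    multiband imagery.
    """

    data: np.ndarray
    transform: Affine
    crs: str | None = None
    nodata: float | None = None

    @property
    def shape(self) -> tuple:
        return self.data.shape[:2]

    @property
    def pixel_area(self) -> float:
        return abs(self.transform.a * self.transform.e
                   - self.transform.b * self.transform.d)

    def with_data(self, data: np.ndarray, nodata=None) -> "Raster":
        """Same georeferencing, new grid (shape preserved on axes 0-1)."""
        if data.shape[:2] != self.shape:
            raise ValueError(f"grid shape {data.shape[:2]} != {self.shape}")
        return replace(self, data=data, nodata=nodata)

    def bounds(self) -> tuple:
        """(minx, miny, maxx, maxy) of the pixel-edge extent."""
        rows, cols = self.shape
        xs, ys = self.transform.xy([0, rows], [0, cols], offset=0.0)
        return float(np.min(xs)), float(np.min(ys)), \
            float(np.max(xs)), float(np.max(ys))


def _epsg_code(crs: str | None) -> int | None:
    if crs is None:
        return None
    return int(str(crs).upper().replace("EPSG:", ""))


def write_geotiff(path, raster: Raster) -> None:
    """Write a Raster as a (Geo)TIFF with georeferencing tags."""
    t = raster.transform
    if not t.is_rectilinear:
        raise ValueError("only north-up (rectilinear) transforms are supported")
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
    ]
    code = _epsg_code(raster.crs)
    if code is not None:
        geographic = is_geographic(raster.crs)
        keys = [1, 1, 0, 3,
                _KEY_GT_MODEL_TYPE, 0, 1, (2 if geographic else 1),
                _KEY_GT_RASTER_TYPE, 0, 1, 1,
                (_KEY_GEOGRAPHIC_TYPE if geographic else _KEY_PROJECTED_CS_TYPE),
                0, 1, code]
        extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keys), tuple(keys)))
    if raster.nodata is not None:
        nod = raster.nodata
        nod_s = str(int(nod)) if float(nod) == int(nod) else repr(float(nod))
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nod_s))
    data = raster.data
    photometric = "rgb" if (data.ndim == 3 and data.shape[2] == 3) else "minisblack"
    tifffile.imwrite(Path(path), data, photometric=photometric,
                     extratags=extratags)


def read_geotiff(path) -> Raster:
    """Read a (Geo)TIFF written by :func:`write_geotiff` (or compatible)."""
    with tifffile.TiffFile(Path(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        transform = Affine(1.0, 0.0, 0.0, 0.0, -1.0, 0.0)
        scale_tag = tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is not None and tie_tag is not None:
            sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
            tie = tie_tag.value
            # tiepoint maps raster (i, j) to model (x, y); standard usage
            # anchors the upper-left corner at (0, 0)
            west = float(tie[3]) - float(tie[0]) * sx
            north = float(tie[4]) + float(tie[1]) * sy
            transform = Affine.from_origin(west, north, sx, sy)
        crs = None
        geo_tag = tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geo_tag is not None:
            vals = list(geo_tag.value)
            for i in range(4, len(vals) - 3, 4):
                key, loc, count, value = vals[i:i + 4]
                if key in (_KEY_PROJECTED_CS_TYPE, _KEY_GEOGRAPHIC_TYPE) and loc == 0:
                    crs = f"EPSG:{value}"
        nodata = None
        nod_tag = tags.get(_TAG_GDAL_NODATA)
        if nod_tag is not None:
            nodata = float(str(nod_tag.value).strip().split()[0])
            if data.dtype.kind in "ui":
                nodata = int(nodata)
    return Raster(data=data, transform=transform, crs=crs, nodata=nodata)
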
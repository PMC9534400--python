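"""Damaged-tree objects: contiguous red or gray pixel groups as polygons.

Connected components use rook (4-neighbour) adjacency — diagonal-touching
pixels form separate objects.  Each component is dissolved into one
polygon traced on pixel boundaries (holes preserved), measured in m²
(pixel count x pixel area), optionally filtered to a crown-sized area
range, and reduced to one interior point per object.  The default area
window of [4, 50] m² corresponds to crown radii of roughly 1–4 m and
suppresses both single-pixel noise and large non-tree patches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon, box, mapping
from shapely.ops import unary_union

from .color_model import CrownClass
from .geo import Raster, is_geographic

__all__ = ["CrownObject", "extract_components", "filter_by_area",
           "interior_points", "write_geojson"]

#: rook (edge-sharing) neighbourhood
_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=np.uint8)

DEFAULT_MIN_AREA = 4.0
DEFAULT_MAX_AREA = 50.0


@dataclass
class CrownObject:
    """One contiguous damaged-crown grouping."""

    crown_class: CrownClass
    polygon: Polygon
    area_m2: float
    pixel_count: int

    @property
    def interior_point(self) -> Point:
        """The centroid when it lies inside the polygon, otherwise a
        representative point guaranteed inside (non-convex shapes)."""
        c = self.polygon.centroid
        if self.polygon.contains(c):
            return c
        return self.polygon.representative_point()


def extract_components(classified: Raster,
                       crown_class: CrownClass) -> list[CrownObject]:
    """Rook-adjacency components of one class, dissolved into polygons.

    Requires a projected (metre-unit) CRS so areas are meaningful.
    Red and gray are extracted independently; never merged.
    """
    if is_geographic(classified.crs):
        raise ValueError(
            f"geographic CRS {classified.crs}: areas in m² are undefined; "
            "project the raster first")
    if classified.data.ndim != 2:
        raise ValueError("classified raster must be single-band")
    crown_class = CrownClass(crown_class)

    mask = classified.data == int(crown_class)
    labels, n = ndimage.label(mask, structure=_ROOK)
    if n == 0:
        return []
    t = classified.transform
    pixel_area = classified.pixel_area
    objects = []
    slices = ndimage.find_objects(labels)
    for comp_id, sl in enumerate(slices, start=1):
        rr, cc = np.nonzero(labels[sl] == comp_id)
        rr = rr + sl[0].start
        cc = cc + sl[1].start
        x0, y0 = t.xy(rr, cc, offset=0.0)
        x1, y1 = t.xy(rr + 1, cc + 1, offset=0.0)
        cells = [box(min(a, c), min(b, d), max(a, c), max(b, d))
                 for a, b, c, d in zip(x0, y0, x1, y1)]
        poly = unary_union(cells)
        objects.append(CrownObject(crown_class=crown_class, polygon=poly,
                                   area_m2=float(poly.area),
                                   pixel_count=int(len(rr))))
    return objects


def filter_by_area(objects,
                   min_area: float = DEFAULT_MIN_AREA,
                   max_area: float = DEFAULT_MAX_AREA) -> list[CrownObject]:
    """Retain objects with min_area <= area <= max_area (both inclusive)."""
    if min_area > max_area:
        raise ValueError(f"min_area {min_area} > max_area {max_area}")
    return [o for o in objects if min_area <= o.area_m2 <= max_area]


def interior_points(objects) -> list[Point]:
    """One guaranteed-interior point per object."""
    pts = []
    for o in objects:
        if o.polygon.is_empty:
            raise ValueError("empty geometry")
        pts.append(o.interior_point)
    return pts


def _feature(geom, props) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_geojson(objects, directory, stem: str = "objects",
                  crs: str | None = None) -> dict:
    """Write polygon and point layers per class as GeoJSON files.

    Produces ``<stem>_{red,gray}_{polygons,points}.geojson`` (only for
    classes present) and returns {layer name: path}.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = {}
    for cls in (CrownClass.RED, CrownClass.GRAY):
        objs = [o for o in objects if o.crown_class == cls]
        if not objs:
            continue
        layers = {
            f"{cls.label}_polygons": [
                _feature(o.polygon, {"class": o.crown_class.label,
                                     "area_m2": o.area_m2,
                                     "pixel_count": o.pixel_count})
                for o in objs],
            f"{cls.label}_points": [
                _feature(o.interior_point, {"class": o.crown_class.label,
                                            "area_m2": o.area_m2,
                                            "pixel_count": o.pixel_count})
                for o in objs],
        }
        for name, features in layers.items():
            fc = {"type": "FeatureCollection", "features": features}
            if crs:
                fc["crs"] = {"type": "name", "properties": {"name": crs}}
            path = directory / f"{stem}_{name}.geojson"
            with open(path, "w") as fh:
                json.dump(fc, fh)
            written[name] = str(path)
    return written
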
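"""Project the pixel model across georeferenced rasters and apply a
coarse forest/non-forest mask.

Classification is strictly per-pixel, so block/tile processing is
bit-identical to whole-image processing.  The forest mask follows the
standard land-cover reclassification: NLCD values 41 (deciduous), 42
(evergreen), 43 (mixed forest) and 90 (woody wetlands) are forest;
everything else is non-forest.  Because the model cannot tell trees from
other objects, classified pixels falling in non-forest cells of the
coarse (30 m) mask are removed.
"""

from __future__ import annotations

import numpy as np

from .color_model import ModelConstants, NODATA_CODE, classify_array
from .geo import Raster

__all__ = ["classify_raster", "build_forest_mask", "apply_mask",
           "DEFAULT_FOREST_VALUES", "CLASS_COLOR_TABLE"]

DEFAULT_FOREST_VALUES = frozenset({41, 42, 43, 90})

#: Display colors for classified outputs (code -> RGB), matching the
#: conventional rendering: orange = red class, light gray = gray class,
#: dark green = green class, black = shadow, white = unclassified.
CLASS_COLOR_TABLE = {
    0: (255, 255, 255),
    1: (230, 120, 30),
    2: (200, 200, 200),
    3: (20, 90, 30),
    4: (0, 0, 0),
}


def classify_raster(image: Raster,
                    constants: ModelConstants,
                    t: float | None = None,
                    bits: int = 8,
                    block_rows: int | None = None) -> Raster:
    """Classify every pixel of a 3-band RGB raster.

    Returns a single-band uint8 raster with the crown-class codes
    (0 unclassified, 1 red, 2 gray, 3 green, 4 shadow, 255 nodata).
    Source nodata (a pixel whose every band equals the nodata value)
    propagates to 255.  ``block_rows`` processes the image in horizontal
    strips; the output is identical either way.
    """
    data = image.data
    if data.ndim != 3 or data.shape[2] != 3:
        raise ValueError(f"expected a (rows, cols, 3) RGB raster, got shape {data.shape}")
    if data.dtype.kind not in "ui":
        raise ValueError(f"expected unsigned integer imagery, got dtype {data.dtype}")
    if t is not None:
        constants = constants.replace(t=t)

    rows = data.shape[0]
    out = np.empty(data.shape[:2], dtype=np.uint8)
    step = block_rows or rows
    for r0 in range(0, rows, step):
        block = data[r0:r0 + step]
        out[r0:r0 + step] = classify_array(block, constants, bits=bits)
    if image.nodata is not None:
        out[np.all(data == image.nodata, axis=2)] = NODATA_CODE
    return image.with_data(out, nodata=NODATA_CODE)


def build_forest_mask(landcover: Raster,
                      forest_values=DEFAULT_FOREST_VALUES) -> Raster:
    """Reclassify a categorical land-cover raster to a binary forest mask
    (1 = forest, 0 = non-forest) at its native resolution."""
    if landcover.data.ndim != 2:
        raise ValueError("land-cover raster must be single-band")
    mask = np.isin(landcover.data, list(forest_values)).astype(np.uint8)
    return landcover.with_data(mask, nodata=None)


def apply_mask(classified: Raster, mask: Raster,
               masked_code: int = NODATA_CODE) -> Raster:
    """Remove classified pixels outside the forest mask.

    Each fine pixel keeps its class only when its center falls inside a
    forest cell of the (possibly coarser) mask; pixels whose centers fall
    in non-forest cells — or outside the mask's extent — are set to
    ``masked_code``.  Both rasters must share a CRS; the lookup is
    nearest-neighbour (pixel-center containment), so masking is
    idempotent.
    """
    if classified.crs != mask.crs:
        raise ValueError(f"CRS mismatch: {classified.crs} vs {mask.crs}")
    cminx, cminy, cmaxx, cmaxy = classified.bounds()
    mminx, mminy, mmaxx, mmaxy = mask.bounds()
    if cminx >= mmaxx or cmaxx <= mminx or cminy >= mmaxy or cmaxy <= mminy:
        raise ValueError("classified raster and mask extents are disjoint")

    rows, cols = classified.shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    x, y = classified.transform.xy(rr, cc)
    mrow, mcol = mask.transform.rowcol(x, y)
    mrow = np.floor(mrow).astype(np.int64)
    mcol = np.floor(mcol).astype(np.int64)
    inside = (mrow >= 0) & (mrow < mask.shape[0]) & \
             (mcol >= 0) & (mcol < mask.shape[1])
    forest = np.zeros((rows, cols), dtype=bool)
    forest[inside] = mask.data[mrow[inside], mcol[inside]] > 0

    out = classified.data.copy()
    out[~forest] = masked_code
    return classified.with_data(out, nodata=classified.nodata)
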
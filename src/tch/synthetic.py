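"""Synthetic scenes and labeled point sets with known crown-class truth.

Class colors are drawn uniformly from HSV boxes chosen to match the
supports of the four score equations — green hues around 1/3, red hues
around 0 (with the brown/orange allowance below 1/6), grays at very low
saturation, shadows at very low value — then converted to RGB and
quantized to the imagery bit depth before classification, so the
channel-equality special cases arise naturally.  The boxes make no claim
of radiometric realism for any particular sensor; they emulate the color
structure the model assumes, which is what makes every pipeline stage
testable without imagery downloads.

Scenes are rectangular class patches on a distinguishable background
(blue "water", which the model leaves unclassified); every draw is fixed
by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .color_model import CrownClass
from .geo import Affine, Raster

__all__ = ["CLASS_HSV_BOXES", "SceneSpec", "PatchSpec", "sample_class_colors",
           "render_scene", "make_training_set"]

#: Default per-class HSV sampling boxes: {class: ((hmin, hmax), (smin, smax),
#: (vmin, vmax))}.  Hue ranges may extend below 0 to wrap around the red
#: anchor.  Documented rationale: green within ±0.066 of the 1/3 anchor;
#: red within ±0.08 of 0 (inside the brown/orange-inclusive support
#: [0, 1/6)); gray near-achromatic at mid brightness; shadow near-black.
CLASS_HSV_BOXES: dict = {
    CrownClass.GREEN: ((0.27, 0.40), (0.35, 0.90), (0.30, 0.90)),
    CrownClass.RED: ((-0.08, 0.08), (0.35, 0.90), (0.30, 0.90)),
    CrownClass.GRAY: ((0.0, 1.0), (0.0, 0.02), (0.35, 0.80)),
    CrownClass.SHADOW: ((0.0, 1.0), (0.0, 0.10), (0.008, 0.05)),
}

#: Background color box (blue water): hue far from every class anchor and
#: bright enough that no score clears the default threshold.
BACKGROUND_HSV_BOX = ((0.55, 0.65), (0.40, 0.80), (0.30, 0.70))

#: Adversarial gray box for degraded-data experiments: grays digitized
#: near-black, indistinguishable from shadow.
NEAR_BLACK_GRAY_BOX = ((0.0, 1.0), (0.0, 0.15), (0.0, 0.06))


def sample_class_colors(crown_class, n: int, seed=None,
                        boxes: dict | None = None,
                        bits: int = 8,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` raw RGB triples for one crown class (or ``"background"``).

    HSV is sampled uniformly in the class box, converted to RGB and
    quantized to the bit depth.  Returns an (n, 3) unsigned integer array.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if crown_class == "background":
        hbox, sbox, vbox = BACKGROUND_HSV_BOX
    else:
        table = CLASS_HSV_BOXES if boxes is None else {**CLASS_HSV_BOXES, **boxes}
        hbox, sbox, vbox = table[CrownClass(crown_class)]
    for name, (lo, hi) in (("saturation", sbox), ("value", vbox)):
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"{name} box {lo, hi} outside [0, 1]")
    if hbox[1] - hbox[0] > 1.0:
        raise ValueError(f"hue box {hbox} wider than the hue circle")
    h = rng.uniform(hbox[0], hbox[1], size=n) % 1.0
    s = rng.uniform(sbox[0], sbox[1], size=n)
    v = rng.uniform(vbox[0], vbox[1], size=n)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    top = 2 ** bits - 1
    dtype = np.uint8 if bits <= 8 else np.uint16
    return np.rint(rgb * top).astype(dtype)


@dataclass(frozen=True)
class PatchSpec:
    """A rectangular patch of one crown class in pixel coordinates."""

    crown_class: CrownClass
    row: int
    col: int
    height: int
    width: int

    def slices(self) -> tuple:
        return slice(self.row, self.row + self.height), \
            slice(self.col, self.col + self.width)


@dataclass(frozen=True)
class SceneSpec:
    """Layout and sampling parameters for a synthetic scene."""

    width: int = 64
    height: int = 64
    pixel_size: float = 1.0
    patches: tuple = ()
    seed: int = 0
    bits: int = 8
    boxes: dict | None = None
    origin: tuple = (500000.0, 4500000.0)
    crs: str = "EPSG:32613"

    def with_patches(self, patches) -> "SceneSpec":
        return replace(self, patches=tuple(patches))


def render_scene(spec: SceneSpec) -> tuple[Raster, Raster]:
    """Render a scene to an RGB raster and its truth-code raster.

    Background pixels get truth code 0 (the model should leave them
    unclassified).  Overlapping patches of different classes are an
    error; same-class overlap is allowed.
    """
    rng = np.random.default_rng(spec.seed)
    top = 2 ** spec.bits - 1
    dtype = np.uint8 if spec.bits <= 8 else np.uint16
    rgb = np.empty((spec.height, spec.width, 3), dtype=dtype)
    truth = np.zeros((spec.height, spec.width), dtype=np.uint8)

    n_bg = spec.height * spec.width
    rgb.reshape(-1, 3)[:] = sample_class_colors(
        "background", n_bg, rng=rng, bits=spec.bits)

    for patch in spec.patches:
        rs, cs = patch.slices()
        if rs.stop > spec.height or cs.stop > spec.width or \
                patch.row < 0 or patch.col < 0:
            raise ValueError(f"patch {patch} outside scene bounds")
        region = truth[rs, cs]
        code = int(CrownClass(patch.crown_class))
        if np.any((region != 0) & (region != code)):
            raise ValueError(f"patch {patch} overlaps a different-class patch")
        n = patch.height * patch.width
        colors = sample_class_colors(patch.crown_class, n, rng=rng,
                                     boxes=spec.boxes, bits=spec.bits)
        rgb[rs, cs] = colors.reshape(patch.height, patch.width, 3)
        truth[rs, cs] = code

    transform = Affine.from_origin(spec.origin[0], spec.origin[1],
                                   spec.pixel_size, spec.pixel_size)
    return (Raster(rgb, transform, crs=spec.crs, nodata=None),
            Raster(truth, transform, crs=spec.crs, nodata=None))


def make_training_set(points_per_class: int = 100,
                      seed: int = 0,
                      strata=None,
                      boxes: dict | None = None,
                      bits: int = 8,
                      cluster_size: int = 1) -> pd.DataFrame:
    """Labeled point table emulating photo-interpreted crown-class points.

    ``strata`` is an iterable of (state, year) pairs, one block of
    ``points_per_class`` points per class per stratum.  ``cluster_size``
    > 1 mimics digitizing several pixels per tree crown: draws within a
    cluster share one crown color center with small HSV jitter.
    """
    if points_per_class < 1:
        raise ValueError("need at least one point per class")
    strata = list(strata) if strata is not None else [("CO", 2019)]
    rng = np.random.default_rng(seed)
    frames = []
    for state, year in strata:
        for cls in (CrownClass.GREEN, CrownClass.RED, CrownClass.GRAY,
                    CrownClass.SHADOW):
            if cluster_size <= 1:
                rgbs = sample_class_colors(cls, points_per_class, rng=rng,
                                           boxes=boxes, bits=bits)
            else:
                chunks = []
                remaining = points_per_class
                table = CLASS_HSV_BOXES if boxes is None else \
                    {**CLASS_HSV_BOXES, **boxes}
                hbox, sbox, vbox = table[cls]
                while remaining > 0:
                    k = min(cluster_size, remaining)
                    center = (rng.uniform(*hbox), rng.uniform(*sbox),
                              rng.uniform(*vbox))
                    jitter = rng.normal(0.0, 0.01, size=(k, 3))
                    hsv = np.clip(np.asarray(center) + jitter,
                                  [hbox[0], sbox[0], vbox[0]],
                                  [hbox[1], sbox[1], vbox[1]])
                    hsv[:, 0] %= 1.0
                    top = 2 ** bits - 1
                    chunks.append(np.rint(hsv_to_rgb(hsv) * top).astype(
                        np.uint8 if bits <= 8 else np.uint16))
                    remaining -= k
                rgbs = np.concatenate(chunks)
            frames.append(pd.DataFrame({
                "class": cls.label,
                "r": rgbs[:, 0].astype(np.int64),
                "g": rgbs[:, 1].astype(np.int64),
                "b": rgbs[:, 2].astype(np.int64),
                "state": state,
                "year": year,
            }))
    return pd.concat(frames, ignore_index=True)
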
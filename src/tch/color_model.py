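"""Per-pixel Tree Crown Health (TCH) classification in HSV color space.

The model partitions HSV color space into four tree-crown condition
classes — green (healthy), red (damaged/dying, including brown and orange
hues), gray (damaged/dead) and shadow — using four score equations driven
by hue, saturation and value respectively.  Each equation has one positive
calibration constant (``c_g``, ``c_r``, ``c_y``, ``c_d``, all >= 2) that
controls how sharply the score decays away from its anchor color.  A pixel
is assigned to the class of its maximum score, provided that maximum
exceeds a classification threshold ``t``; otherwise it is left
unclassified.

Scoring pipeline for a raw RGB pixel:

1. max-normalize channels to [0, 1] by the bit depth,
2. apply the blue-channel adjustment that breaks exact green/red hue
   anchors arising from channel-equal pixels (see
   :func:`apply_blue_adjustment`),
3. convert to HSV (hexcone model; H in [0, 1), red at 0, green at 1/3),
4. rescale hue for the green and red classes, score all four classes,
5. if S = 0 (achromatic pixel), replace the gray score Y with Y - D so
   that dark achromatic pixels fall to shadow rather than gray; hue is
   undefined there, so the hue-based scores G and R are not in play,
6. take X = max{G, R, Y, D}; assign the argmax class when X > t.

Two APIs are provided: scalar functions mirroring the equations one by
one, and a vectorized array API (:func:`classify_array`) used for rasters.
Both produce bit-identical results.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "CrownClass",
    "ModelConstants",
    "ClassScores",
    "MEDIAN_CONSTANTS",
    "DEFAULT_THRESHOLD",
    "normalize_rgb",
    "apply_blue_adjustment",
    "rgb_to_hsv",
    "rescale_hue_green",
    "rescale_hue_red",
    "score_green",
    "score_red",
    "score_gray",
    "score_shadow",
    "classify_pixel",
    "classify_array",
    "pixel_features",
]

# Exact binary fractions are not representable for 1/3 and 1/6; fixing the
# constants here keeps the scalar and vectorized paths bit-identical.
ONE_THIRD = 1.0 / 3.0
ONE_SIXTH = 1.0 / 6.0

DEFAULT_THRESHOLD = 0.1


class CrownClass(IntEnum):
    """Crown condition classes and their raster codes.

    Code 0 is reserved for pixels left unclassified by the model (maximum
    score at or below the threshold) and 255 for nodata / masked-out
    pixels in raster products.
    """

    UNCLASSIFIED = 0
    RED = 1
    GRAY = 2
    GREEN = 3
    SHADOW = 4

    @classmethod
    def from_label(cls, label: str) -> "CrownClass":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown crown class label: {label!r}") from None

    @property
    def label(self) -> str:
        return self.name.lower()


NODATA_CODE = 255

#: Argmax tie precedence (ties occur only on quantized inputs).
_PRECEDENCE = (CrownClass.GREEN, CrownClass.RED, CrownClass.GRAY, CrownClass.SHADOW)


@dataclass(frozen=True)
class ModelConstants:
    """Calibration constants of the four score equations plus threshold.

    All four constants must be >= 2 (the score curves are defined for all
    values >= 2); ``t`` is the minimum classification threshold in [0, 1).
    """

    c_g: float = 5.0
    c_r: float = 5.0
    c_y: float = 1e7
    c_d: float = 1e4
    t: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("c_g", "c_r", "c_y", "c_d"):
            v = getattr(self, name)
            if not (v >= 2):
                raise ValueError(f"{name} must be >= 2, got {v}")
        if not (0 <= self.t < 1):
            raise ValueError(f"t must be in [0, 1), got {self.t}")

    def replace(self, **kw) -> "ModelConstants":
        d = {"c_g": self.c_g, "c_r": self.c_r, "c_y": self.c_y,
             "c_d": self.c_d, "t": self.t}
        d.update(kw)
        return ModelConstants(**d)

    def to_dict(self) -> dict:
        return {"c_g": self.c_g, "c_r": self.c_r, "c_y": self.c_y,
                "c_d": self.c_d, "t": self.t}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConstants":
        return cls(**{k: d[k] for k in ("c_g", "c_r", "c_y", "c_d", "t") if k in d})


#: Median optimal constants across calibrated state x year models; the
#: transferable "global" parameterization.
MEDIAN_CONSTANTS = ModelConstants(c_g=5.0, c_r=5.0, c_y=1e7, c_d=1e4, t=0.1)


@dataclass(frozen=True)
class ClassScores:
    """Per-pixel class scores; Y is the post-recalculation gray score."""

    G: float
    R: float
    Y: float
    D: float

    @property
    def X(self) -> float:
        return max(self.G, self.R, self.Y, self.D)


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------

def normalize_rgb(r: int, g: int, b: int, bits: int = 8) -> tuple[float, float, float]:
    """Max-normalize raw unsigned channels to [0, 1] by bit depth."""
    top = 2 ** bits - 1
    for name, v in (("r", r), ("g", g), ("b", b)):
        if v != int(v):
            raise ValueError(f"raw channel {name} must be an integer, got {v!r}")
        if not (0 <= v <= top):
            raise ValueError(f"raw channel {name}={v} outside [0, {top}]")
    return r / top, g / top, b / top


def apply_blue_adjustment(r: float, g: float, b: float,
                          bits: int = 8) -> tuple[float, float, float]:
    """Decrement blue by 1/2^bits on pixels whose hue would sit exactly on
    the green or red anchor.

    When b == r with g > r the hue is exactly 1/3 (green anchor), and when
    b == g with r > g it is exactly 0 (red anchor), independent of the
    other two channels — so G or R would reach their maximum regardless of
    saturation or value.  Lowering blue by one quantization step breaks the
    exact anchor.  All-equal pixels (r = g = b) are achromatic and are
    handled by the S = 0 recalculation instead.  Blue is floored at 0 (a
    zero-blue pixel is left unchanged).
    """
    if (b == r and g > r) or (b == g and r > g):
        b = max(b - 1.0 / 2 ** bits, 0.0)
    return r, g, b


def rgb_to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Hexcone RGB -> HSV on [0, 1] channels; H in [0, 1), red at 0."""
    return colorsys.rgb_to_hsv(r, g, b)


def rescale_hue_green(h: float) -> float:
    """Rescaled green hue Hg = 1 - |H - 1/3| / (1/6); 1 at the green anchor,
    positive exactly on H in (1/6, 1/2)."""
    return 1.0 - abs(h - ONE_THIRD) / ONE_SIXTH


def rescale_hue_red(h: float) -> float:
    """Rescaled red hue Hr = |1/2 - H| / (1/6) - 2; 1 at H = 0 or 1,
    positive exactly on H < 1/6 or H > 5/6."""
    return abs(0.5 - h) / ONE_SIXTH - 2.0


def _check_constant(c: float, name: str) -> None:
    if not (c >= 2):
        raise ValueError(f"{name} must be >= 2, got {c}")


def _pow(c: float, e: float) -> float:
    # numpy's pow can differ from libm's in the last ulp; the scalar path
    # goes through the same ufunc as the array path to stay bit-identical
    return float(np.power(np.float64(c), np.float64(e)))


def score_green(hg: float, c_g: float) -> float:
    """Green score G = (c_g**Hg - 1)/(c_g - 1) for Hg >= 0, else 0."""
    _check_constant(c_g, "c_g")
    if hg < 0:
        return 0.0
    return (_pow(c_g, hg) - 1.0) / (c_g - 1.0)


def score_red(hr: float, c_r: float) -> float:
    """Red score R = (c_r**Hr - 1)/(c_r - 1) for Hr >= 0, else 0."""
    _check_constant(c_r, "c_r")
    if hr < 0:
        return 0.0
    return (_pow(c_r, hr) - 1.0) / (c_r - 1.0)


def score_gray(s: float, c_y: float) -> float:
    """Gray score Y = (c_y**(1-S) - 1)/(c_y - 1); 1 at S = 0, 0 at S = 1."""
    _check_constant(c_y, "c_y")
    return (_pow(c_y, 1.0 - s) - 1.0) / (c_y - 1.0)


def score_shadow(v: float, c_d: float) -> float:
    """Shadow score D = (c_d**(1-V) - 1)/(c_d - 1); 1 at V = 0, 0 at V = 1."""
    _check_constant(c_d, "c_d")
    return (_pow(c_d, 1.0 - v) - 1.0) / (c_d - 1.0)


def classify_pixel(r: int, g: int, b: int,
                   constants: ModelConstants = MEDIAN_CONSTANTS,
                   bits: int = 8,
                   blue_adjustment: bool = True,
                   ) -> tuple[CrownClass, ClassScores]:
    """Classify one raw RGB pixel; returns the class and the four scores.

    ``blue_adjustment=False`` disables the anchor-breaking blue decrement
    (useful for demonstrating the pathology it corrects).
    """
    rn, gn, bn = normalize_rgb(r, g, b, bits)
    if blue_adjustment:
        rn, gn, bn = apply_blue_adjustment(rn, gn, bn, bits)
    h, s, v = rgb_to_hsv(rn, gn, bn)
    if s == 0.0:
        # achromatic: hue undefined, gray and shadow compete; Y recalculated
        # as Y - D so near-black pixels fall to shadow, not gray
        G = R = 0.0
        y = score_gray(0.0, constants.c_y)
        d = score_shadow(v, constants.c_d)
        y = y - d
    else:
        G = score_green(rescale_hue_green(h), constants.c_g)
        R = score_red(rescale_hue_red(h), constants.c_r)
        y = score_gray(s, constants.c_y)
        d = score_shadow(v, constants.c_d)
    scores = ClassScores(G=G, R=R, Y=y, D=d)
    x = scores.X
    if not (x > constants.t):
        return CrownClass.UNCLASSIFIED, scores
    by_class = {CrownClass.GREEN: G, CrownClass.RED: R,
                CrownClass.GRAY: y, CrownClass.SHADOW: d}
    for cls in _PRECEDENCE:
        if by_class[cls] == x:
            return cls, scores
    raise AssertionError("unreachable: X is the max of the four scores")


# ---------------------------------------------------------------------------
# vectorized path
# ---------------------------------------------------------------------------

def _rgb_to_hsv_array(r: np.ndarray, g: np.ndarray, b: np.ndarray):
    """Vectorized hexcone conversion, arithmetic-identical to colorsys."""
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    rangec = maxc - minc
    v = maxc
    achromatic = rangec == 0.0
    safe_range = np.where(achromatic, 1.0, rangec)
    safe_max = np.where(maxc == 0.0, 1.0, maxc)
    s = np.where(achromatic, 0.0, rangec / safe_max)
    rc = (maxc - r) / safe_range
    gc = (maxc - g) / safe_range
    bc = (maxc - b) / safe_range
    h = np.where(r == maxc, bc - gc,
                 np.where(g == maxc, 2.0 + rc - bc, 4.0 + gc - rc))
    h = (h / 6.0) % 1.0
    h = np.where(achromatic, 0.0, h)
    return h, s, v


def pixel_features(rgb: np.ndarray, bits: int = 8,
                   blue_adjustment: bool = True):
    """Constant-independent per-pixel quantities for raw RGB input.

    Parameters
    ----------
    rgb
        Unsigned integer array with a trailing axis of length 3 (R, G, B).

    Returns
    -------
    hg, hr, s, v, achromatic
        Rescaled hues, saturation, value and the S = 0 mask, each with the
        input's leading shape.  These feed the score equations and depend
        only on the pixel, not on the model constants, so they can be
        computed once and reused across many constant combinations.
    """
    rgb = np.asarray(rgb)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected trailing axis of length 3, got shape {rgb.shape}")
    if rgb.dtype.kind not in "ui":
        raise ValueError(f"expected unsigned integer RGB, got dtype {rgb.dtype}")
    top = 2 ** bits - 1
    if rgb.size and (rgb.min() < 0 or rgb.max() > top):
        raise ValueError(f"channel values outside [0, {top}] for {bits}-bit input")

    r = rgb[..., 0].astype(np.float64) / top
    g = rgb[..., 1].astype(np.float64) / top
    b = rgb[..., 2].astype(np.float64) / top
    if blue_adjustment:
        trigger = ((b == r) & (g > r)) | ((b == g) & (r > g))
        b = np.where(trigger, np.maximum(b - 1.0 / 2 ** bits, 0.0), b)
    h, s, v = _rgb_to_hsv_array(r, g, b)
    hg = 1.0 - np.abs(h - ONE_THIRD) / ONE_SIXTH
    hr = np.abs(0.5 - h) / ONE_SIXTH - 2.0
    return hg, hr, s, v, (s == 0.0)


def _scores_from_features(hg, hr, s, v, achromatic, constants: ModelConstants):
    G = np.where(hg >= 0.0, (constants.c_g ** np.maximum(hg, 0.0) - 1.0)
                 / (constants.c_g - 1.0), 0.0)
    R = np.where(hr >= 0.0, (constants.c_r ** np.maximum(hr, 0.0) - 1.0)
                 / (constants.c_r - 1.0), 0.0)
    Y = (constants.c_y ** (1.0 - s) - 1.0) / (constants.c_y - 1.0)
    D = (constants.c_d ** (1.0 - v) - 1.0) / (constants.c_d - 1.0)
    G = np.where(achromatic, 0.0, G)
    R = np.where(achromatic, 0.0, R)
    Y = np.where(achromatic, Y - D, Y)
    return G, R, Y, D


def _assign(G, R, Y, D, t):
    X = np.maximum(np.maximum(G, R), np.maximum(Y, D))
    # reverse precedence so earlier classes overwrite later ones on ties
    cls = np.full(X.shape, int(CrownClass.SHADOW), dtype=np.uint8)
    cls[Y == X] = int(CrownClass.GRAY)
    cls[R == X] = int(CrownClass.RED)
    cls[G == X] = int(CrownClass.GREEN)
    cls[~(X > t)] = int(CrownClass.UNCLASSIFIED)
    return cls, X


def classify_array(rgb: np.ndarray,
                   constants: ModelConstants = MEDIAN_CONSTANTS,
                   bits: int = 8,
                   blue_adjustment: bool = True,
                   return_scores: bool = False):
    """Classify an array of raw RGB pixels.

    Parameters
    ----------
    rgb
        Unsigned integer array of shape (..., 3).
    return_scores
        If True, also return the (G, R, Y, D) score arrays (Y is the
        post-recalculation gray score).

    Returns
    -------
    codes : uint8 array of the leading shape, values per :class:`CrownClass`
    scores : tuple of four float64 arrays, only if ``return_scores``
    """
    hg, hr, s, v, ach = pixel_features(rgb, bits=bits,
                                       blue_adjustment=blue_adjustment)
    G, R, Y, D = _scores_from_features(hg, hr, s, v, ach, constants)
    codes, _ = _assign(G, R, Y, D, constants.t)
    if return_scores:
        return codes, (G, R, Y, D)
    return codes
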
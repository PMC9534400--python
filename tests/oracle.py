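"""Independent scalar reference for the crown classification model.

Evaluates the eight score equations (with both special-case
adjustments) pixel by pixel in pure Python, using stdlib ``colorsys``
for the textbook RGB->HSV conversion.  Deliberately kept free of any
import from the package's numerical path so it can serve as an oracle
for the vectorized classifier.
"""

import colorsys

# class codes (must mirror the package's raster convention)
UNCLASSIFIED, RED, GRAY, GREEN, SHADOW = 0, 1, 2, 3, 4


def classify_pixel_reference(r, g, b, c_g=5.0, c_r=5.0, c_y=1e7, c_d=1e4,
                             t=0.1, bits=8, blue_adjustment=True):
    """Return (code, (G, R, Y, D)) for one raw RGB pixel."""
    top = 2 ** bits - 1
    rn, gn, bn = r / top, g / top, b / top
    if blue_adjustment and ((bn == rn and gn > rn) or (bn == gn and rn > gn)):
        bn = max(bn - 1.0 / 2 ** bits, 0.0)
    h, s, v = colorsys.rgb_to_hsv(rn, gn, bn)
    if s == 0.0:
        d = (c_d ** (1.0 - v) - 1.0) / (c_d - 1.0)
        y = (c_y ** (1.0 - 0.0) - 1.0) / (c_y - 1.0) - d
        G = R = 0.0
    else:
        hg = 1.0 - abs(h - 1.0 / 3.0) / (1.0 / 6.0)
        hr = abs(0.5 - h) / (1.0 / 6.0) - 2.0
        G = (c_g ** hg - 1.0) / (c_g - 1.0) if hg >= 0 else 0.0
        R = (c_r ** hr - 1.0) / (c_r - 1.0) if hr >= 0 else 0.0
        y = (c_y ** (1.0 - s) - 1.0) / (c_y - 1.0)
        d = (c_d ** (1.0 - v) - 1.0) / (c_d - 1.0)
    x = max(G, R, y, d)
    if not x > t:
        return UNCLASSIFIED, (G, R, y, d)
    # tie precedence: green > red > gray > shadow
    if G == x:
        return GREEN, (G, R, y, d)
    if R == x:
        return RED, (G, R, y, d)
    if y == x:
        return GRAY, (G, R, y, d)
    return SHADOW, (G, R, y, d)
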
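# tch — Tree Crown Health classification from RGB aerial imagery

`tch` implements the Tree Crown Health (TCH) model: a supervised,
equation-based classifier that partitions HSV color space into four
tree-crown condition classes — **green** (healthy crowns), **red**
(damaged or dying crowns, including brown/orange hues), **gray** (dead
crowns) and **shadow** — on high-resolution 3-band RGB imagery
(NAIP-style, 0.6–1 m). It is aimed at forest-health analysts who need
wall-to-wall maps of individual damaged or dead trees from freely
available aerial imagery, without multispectral or lidar inputs.

Beyond the pixel model, the package provides the full workflow around it:
training-point management and 90/10 partitioning, exhaustive grid-search
calibration of the model constants, accuracy assessment (overall
accuracy, Cohen's κ, per-class sensitivity), raster-scale projection with
land-cover forest masking, and extraction of damaged-tree objects
(polygons and interior points) from contiguous red/gray pixels.

## The model

Each pixel's RGB values are max-normalized by bit depth and converted to
HSV with H, S, V ∈ [0, 1] (red at H = 0, green at H = 1/3). Hue is first
rescaled so each color class peaks at 1 and stays positive within ±1/6 of
its anchor:

    Hg = 1 − |H − 1/3| / (1/6)          (green; > 0 for 1/6 < H < 1/2)
    Hr = |1/2 − H| / (1/6) − 2          (red;   > 0 for H < 1/6 or H > 5/6)

Four scores are then computed from one calibration constant each
(c_g, c_r, c_y, c_d, all ≥ 2):

    G = (c_g^Hg − 1) / (c_g − 1)        if Hg ≥ 0, else 0
    R = (c_r^Hr − 1) / (c_r − 1)        if Hr ≥ 0, else 0
    Y = (c_y^(1−S) − 1) / (c_y − 1)     (gray: maximal at S = 0)
    D = (c_d^(1−V) − 1) / (c_d − 1)     (shadow: maximal at V = 0)

The pixel takes the class of X = max{G, R, Y, D} provided X > t
(default t = 0.1); otherwise it is left unclassified. Two special cases
keep the geometry honest: pixels whose blue channel equals red or green
(with the third channel larger) would sit exactly on a hue anchor
regardless of S and V, so blue is decremented by one quantization step
(1/256 for 8-bit) before conversion; and for achromatic pixels (S = 0)
the gray score is recalculated as Y − D so that dark objects fall to
shadow rather than gray.

Constants are calibrated per imagery stratum (state × year) by scanning
all 16,900 combinations of a fixed grid and keeping the combination with
the highest mean per-class sensitivity; calibrations whose minimum class
sensitivity falls below 0.7 are flagged as not retained. The median of
the per-stratum optima (c_g = 5, c_r = 5, c_y = 10⁷, c_d = 10⁴) serves
as a transferable global parameterization and is the package default.

## Worked example

```python
from tch import classify_pixel, MEDIAN_CONSTANTS

for px in [(76, 175, 80), (180, 60, 50), (128, 128, 128), (10, 10, 10)]:
    cls, s = classify_pixel(*px, MEDIAN_CONSTANTS)
    print(f"{px} -> {cls.name:6s} G={s.G:.3f} R={s.R:.3f} "
          f"Y={s.Y:.3f} D={s.D:.3f}")
```

prints

```
(76, 175, 80) -> GREEN  G=0.921 R=0.000 Y=0.000 D=0.002
(180, 60, 50) -> RED    G=0.000 R=0.854 Y=0.000 D=0.001
(128, 128, 128) -> GRAY   G=0.000 R=0.000 Y=0.990 D=0.010
(10, 10, 10) -> SHADOW G=0.000 R=0.000 Y=0.303 D=0.697
```

The leafy green pixel scores 0.921 on the green curve (its hue is close
to 1/3); the brick red pixel 0.854 on red; the mid-gray pixel is
achromatic, so gray and shadow split Y = 1 between them as Y − D = 0.990
vs D = 0.010; the near-black pixel reverses that split (D = 0.697), which
is exactly the dark-pixel pathology the S = 0 recalculation fixes.

The same model runs over rasters and through a complete mapping workflow
from the shell:

```sh
tch simulate --seed 42 --out-image scene.tif --out-truth truth.tif \
             --out-points points.csv
tch optimize --points points.csv --out constants.json
tch classify --image scene.tif --constants constants.json --out classes.tif
tch extract  --classes classes.tif --min-area 4 --max-area 50 --out objects/
```

`classes.tif` is a single-band GeoTIFF (0 unclassified, 1 red, 2 gray,
3 green, 4 shadow, 255 nodata/masked); `objects/` receives GeoJSON layers
of red/gray crown polygons and their interior points with `area_m2` and
`pixel_count` fields. A land-cover raster passed via `--mask` removes
predictions outside forest (codes 41, 42, 43, 90 are treated as forest).

The functions behind these commands (`read_points`, `split_train_test`,
`optimize_constants`, `evaluate_model`, …) accept any point table in the
documented CSV/GeoJSON schema, so the same calibration and evaluation
workflow applies directly to real photo-interpreted crown points.

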
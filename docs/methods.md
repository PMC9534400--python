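# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the known limitations of the `tch` package.

## The classification model

The model is a fixed-form, four-class scorer in HSV color space. The
premise is that crown condition maps onto the three HSV axes almost
orthogonally: hue separates healthy green foliage from the red/brown
signatures of dying crowns; saturation separates chromatic vegetation
from the washed-out gray of dead wood; value isolates shadow. Each class
gets one monotone score curve with a single shape constant, and the pixel
takes the argmax class when the winning score exceeds a threshold `t`.

Given channels normalized to [0, 1] (division by 2^bits − 1) and hexcone
HSV, the green and red hue rescalings are

    Hg = 1 − |H − 1/3|/(1/6),     Hr = |1/2 − H|/(1/6) − 2,

linear tents that peak at 1 on their anchors (H = 1/3 for green, H = 0/1
for red) and cross zero exactly 1/6 away. The red support therefore
covers orange/brown/yellow hues below 1/6 and magenta-tinged hues above
5/6 — both genuine damage signatures — while the green support admits
yellow-green foliage. A hue exactly at 1/6 scores zero on both curves;
no extra yellow tie rule is needed because the curves themselves decide
(below 1/6 only R is positive, above it only G).

The four scores are exponential ramps in the rescaled coordinates,

    G = (c_g^Hg − 1)/(c_g − 1)   (0 when Hg < 0)
    R = (c_r^Hr − 1)/(c_r − 1)   (0 when Hr < 0)
    Y = (c_y^(1−S) − 1)/(c_y − 1)
    D = (c_d^(1−V) − 1)/(c_d − 1)

each mapping its argument's [0, 1] range onto [0, 1] with curvature set
by the constant: at c = 2 the curve is 2^x − 1 (nearly linear), and as
c grows the score concentrates ever more tightly at the anchor. The
constants are restricted to c ≥ 2, where the family is well behaved.

### Special cases

Two corrections handle degeneracies of quantized imagery:

* **Blue-channel adjustment.** When b = r with g > r, the hue is exactly
  1/3 whatever the other channels do; when b = g with r > g it is
  exactly 0. Either way a hue score hits its maximum of 1 independent of
  saturation and value — e.g. the dull pixel (100, 101, 100) would score
  G = 1 and classify green. Blue is therefore decremented by one
  quantization step (1/2^bits, floored at 0) before conversion, which
  breaks the exact anchor; the same pixel then correctly classifies
  gray. Pixels with b = 0 are left unchanged — in the first brightness
  quantum a pixel such as (1, 0, 0) keeps hue exactly 0 at full
  saturation and scores R = 1; such pixels are vanishingly rare in real
  imagery. All-equal pixels (r = g = b) are excluded from the trigger:
  they are achromatic and belong to the next case.

* **Achromatic recalculation.** At S = 0 the gray score is exactly 1
  regardless of brightness, so black pixels would classify gray. For
  S = 0 pixels the gray score is recalculated as Y − D, making gray and
  shadow complementary in brightness (the crossover sits where D = 1/2),
  and the hue scores are set to 0 because hue is undefined for
  achromatic pixels. Classification of achromatic pixels thus reduces
  to a gray-vs-shadow decision, which is the intended semantics.

### Numerical conventions

* All score math is float64. Channel-equality tests on raw integers are
  exact (no epsilon).
* Argmax ties (possible only on quantized inputs, e.g. two scores both
  exactly 0 or 1) resolve by fixed precedence green > red > gray >
  shadow.
* The threshold comparison is strict (X > t); default t = 0.1.
* The scalar and vectorized APIs are bit-identical. The only
  non-trivially reproducible operation is `pow`, whose SIMD kernels can
  differ from libm by one ulp; the scalar path therefore routes through
  the same numpy ufunc as the array path. The hexcone conversion in the
  vectorized path replicates the arithmetic (and branch order) of the
  scalar conversion exactly.

## Calibration

Constants are fitted per imagery stratum (state × year) by exhaustive
scan of a fixed grid — {2, 5, 10, 20, 30, 40, 50, 60, 100, 10³, 10⁴,
10⁵, 10⁶} for c_g and c_r, {2, 5, 10, 10², …, 10⁸} for c_y and c_d;
13·13·10·10 = 16,900 combinations. Every training pixel is classified
under every combination; the objective is the mean of the four per-class
sensitivities (TPR), with unclassified predictions counting against
sensitivity. Ties go to the first combination in ascending lexicographic
(c_g, c_r, c_y, c_d) order, making the scan deterministic. A calibration
is retained only if its minimum class TPR is ≥ 0.7; lower values
indicate imagery or interpretation quality too poor to trust.

Because H, S and V do not depend on the constants, the per-pixel
features are computed once and reused across all combinations. This
caching is contractually identical to naive re-evaluation (tested), and
brings a full scan on a few hundred points to a couple of seconds.

The per-parameter median of many per-stratum optima gives a single
transferable "global" parameterization; the package ships
(c_g, c_r, c_y, c_d) = (5, 5, 10⁷, 10⁴) with t = 0.1 as
`MEDIAN_CONSTANTS`.

## Evaluation

Within each stratum, classes with ≥ 50 points are split 90/10
(test size = round(0.1·n), at least 1); smaller classes contribute all
points to training. The split is seeded, stratified by class within
stratum, and never mixes strata. Evaluation on the withheld points
reports overall accuracy (trace over total; unclassified predictions are
errors), Cohen's κ ((p_o − p_e)/(1 − p_e) with marginal-based p_e;
unclassified predictions enter the marginals as a fifth category, with a
switch to drop them instead), and per-class TPR — but only when every
class has at least 5 testing points; otherwise the report is flagged
ineligible and metrics are withheld. Each report also names the
lowest-TPR class and the prediction that absorbed most of its errors,
the standard confusion taxonomy for this model family (shadow→gray,
gray↔red, green→shadow).

## Raster projection, masking, objects

Raster classification is strictly per-pixel, so tiled processing is
bit-identical to whole-image processing; source nodata propagates to the
output nodata code (255). The forest mask reclassifies a categorical
land-cover raster (forest = {41, 42, 43, 90}, the NLCD forest codes) and
is applied by pixel-center containment: a fine pixel survives only if
its center falls in a forest cell of the coarse grid. Centers falling
outside the mask extent are masked (conservative). Mask application is
idempotent. Reprojection between CRSs is not supported — classified
raster and mask must share a CRS — and the rule for deciding whether a
CRS is geographic is an EPSG-range heuristic (4326 and 4000–4999),
documented here because the object extractor refuses degree-unit CRSs.

Damaged-tree objects are rook-adjacency (4-connectivity) connected
components of red or gray pixels — never merged across the two classes —
dissolved into polygons traced on pixel boundaries with holes preserved,
so polygon area equals pixel count × pixel area exactly. The area filter
keeps objects with 4 m² ≤ area ≤ 50 m² (inclusive; configurable), the
range corresponding to crown radii of roughly 1–4 m at 1 m pixels. Each
object is reduced to one point guaranteed inside the polygon: the
centroid when it is interior, otherwise a representative interior point
(relevant for C-shaped components). Outputs are GeoJSON layers; raster
I/O uses GeoTIFF tags (ModelPixelScale/ModelTiepoint/GeoKeyDirectory)
written through tifffile, supporting north-up transforms only.

## Synthetic data

The generator draws class colors uniformly from HSV boxes, converts to
RGB and quantizes to the imagery bit depth before classification, so
channel-equality special cases occur naturally. The default boxes are

| class  | hue          | saturation | value        |
|--------|--------------|------------|--------------|
| green  | 0.27–0.40    | 0.35–0.90  | 0.30–0.90    |
| red    | −0.08–0.08 (wraps) | 0.35–0.90 | 0.30–0.90 |
| gray   | any          | 0.00–0.02  | 0.35–0.80    |
| shadow | any          | 0.00–0.10  | 0.008–0.05   |

chosen so each class sits inside its score-function support with margins
that survive 8-bit quantization: under the default global constants,
green/red/gray draws re-classify to their generating class at ≥ 99% and
shadow draws at 100%. The shadow value floor of 2/255 avoids the first
brightness quantum, where quantization makes hue and saturation
degenerate (a pixel like (1, 0, 0) is mathematically a fully saturated
red). The background box (hue 0.55–0.65, blue "water") is constructed so
every score stays at or below t = 0.1, exercising the unclassified
outcome. A near-black gray box is provided for degraded-data
experiments, where gray and shadow become inseparable and calibration
fails the 0.7 retention rule.

What the generator does **not** emulate: sensor noise, color-balancing
drift between imagery vendors and years, phenology, mixed pixels at
crown edges, or spatial texture within crowns. Passing tests on
synthetic scenes therefore demonstrate the correctness of the equations,
calibration, and geoprocessing — not field-level accuracy on real
imagery, which depends on training-point quality and imagery
consistency.

Scenes place rectangular class patches on the background at 1 m pixels
in a projected CRS (default EPSG:32613); overlapping patches of
different classes are rejected. Point tables carry (state, year) stratum
metadata and can mimic clustered digitizing (several pixels per crown
sharing a color center).

## Problem sizes

The shipped study sizes keep the full workflow quick while exercising
every code path at meaningful scale: equation-fidelity checks compare
the vectorized and scalar paths on 10⁶ random pixels; calibration runs
the complete 16,900-combination grid on 4 × 100-point training sets
(plus 4 × 120 per stratum in the acceptance script); the end-to-end
scene is 256 × 256 at 1 m with a 30 m mask grid. These complete in a few
seconds to a few tens of seconds on one CPU.

## Known limitations

* The model has no concept of trees: commission errors on any red, gray
  or dark non-tree object are expected, which is why the land-cover mask
  and the crown-sized area filter exist.
* Constants trade sensitivity between classes; a single global set can
  be suboptimal for imagery with unusual color balance.
* Only north-up, axis-aligned rasters are supported; no CRS
  reprojection.
* Near-infrared data, species attribution, causal agents, and multi-date
  change detection are out of scope.
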
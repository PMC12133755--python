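# Methods

## The phenotype and the pipeline

Internal bruising in blueberry — cell damage under an intact skin — becomes
visible as discolored flesh once a berry is cut along its equator. The
package quantifies it per berry half as the **bruising ratio**

    rho = bruise-region pixels / cross-section pixels,  rho in [0, 1],

on top-down photographs of many sliced halves laid on white paper. The
computation is a three-stage cascade: (1) detect each berry half with a
bounding box, (2) segment the berry cross-section inside a padded crop,
(3) segment the bruised flesh inside the cross-section. The bruise mask is
clipped to the cross-section mask before counting, so rho ≤ 1 regardless of
how a backend over-predicts; ratios are therefore invariant to the crop
padding. Berries whose segmentation fails get a null ratio and are excluded
from aggregates instead of aborting the batch.

All three stages are pluggable behind one contract, so the orchestration is
validated independently of any particular model: injecting the generator's
exact masks as backends must (and does, bit-exactly) reproduce the known
ratios, while trained-model outputs can be ingested as YOLO-dialect label
files without any learning-framework dependency.

## Pixel-grid conventions

Boxes are half-open integer rectangles `[x0, x1) x [y0, y1)`, so areas are
products with no ±1 corrections. Polygon vertices are normalized to [0, 1];
rasterization follows the **pixel-center even-odd rule**: a pixel belongs to
a polygon iff its center `(j + 0.5, i + 0.5)` lies inside under
crossing-number counting. The rule is unambiguous and brute-force testable;
its one tie-break is that a center lying *exactly on* an edge follows the
ray-side convention, so mirror symmetry of rasterized areas holds for
polygons in generic position (the property tests use such polygons; the
synthetic generator produces them with probability 1).

## Synthetic plates

The generator emulates the imaging protocol end to end so that every
accuracy claim has exact ground truth:

* **Geometry.** Berry halves are non-overlapping rotated ellipses
  (rejection-sampled placement, ≥ 6 px clearance), radius 40–60 px on a
  960 px plate by default, axis ratio 0.72–0.98, with a skin annulus of
  thickness 12 % of the radius.
* **Bruise.** Impact bruising starts at the contact point on the rim and
  spreads toward the center, giving a triangular cross-section; it is
  modeled as a circular sector of flesh anchored at a random rim angle. The
  sector half-width is solved by bisection (40 iterations) so the rasterized
  bruise area hits a target fraction of the rasterized berry area; the
  realized pixel quotient is recorded as `true_ratio`. Discretization puts
  realized ratios within ±0.002 of the target at radius 60 px, well inside
  the ±0.02 the downstream tests assume. Targets are drawn
  uniform(0.05, 0.35) by default and are capped by the flesh fraction,
  since bruising discolors flesh, not skin.
* **Color.** Background (245, 245, 240), skin (45, 35, 80), flesh
  (225, 230, 190), bruise (150, 75, 60), per-berry uniform jitter ±10,
  plus Gaussian pixel noise (sd 3 by default — the low-noise regime of a
  controlled photography setup). No colorimetric calibration is implied;
  the values echo white paper, dark blue-purple skin, pale flesh, and
  reddish-brown bruised tissue.
* **Determinism.** One `numpy` Generator seeded from `(seed, plate_index)`
  drives everything; identical configs are bit-identical, and plates of a
  batch can be generated independently.

What the generator does **not** emulate: specular highlights, shadows, seed
cavities, berry-to-berry contact, non-impact discoloration, and camera
optics. Passing tests therefore certify the pipeline's logic and its
behavior under the stated geometry/color model, not performance on real
photographs; on real data the classical backends are a baseline and
trained-model predictions should be supplied as label files.

## Classical reference backends

* **Detector**: global Otsu on grayscale isolates dark-rimmed objects;
  closing (disk r=3) → hole filling → opening solidifies each berry (the
  pale flesh interior thresholds as background, so filling must precede
  opening or a broken skin ring loses the berry); components filtered by
  area (min 500 px); confidence is the area-normalized score
  `min(1, area / (2·area_min))`.
* **Cross-section segmenter**: background color estimated as the median of
  the crop border pixels; Otsu on the RGB distance; largest component,
  holes filled. An Otsu threshold below 20 (8-bit color distance) means the
  crop has no berry and raises a per-berry failure.
* **Bruise segmenter**: the berry mask is shrunk past the skin via the
  Euclidean distance transform (depth 13 % of the equivalent radius,
  slightly more than the generated 12 % skin so the flesh estimate stays
  inside true flesh); within that flesh a redness index (R − G) is
  thresholded by Otsu. A contrast guard — index spread (p99.5 − p50) below
  30 — declares the berry bruise-free, preventing Otsu from splitting pure
  noise on healthy berries. Components under 40 px are dropped; the result
  is clipped to the berry mask.

On 20 seeded plates × 20 berries these backends give detection F1 = 1.0 and
mean absolute ratio error ≈ 0.003 (the acceptance script recomputes both).

## Evaluation metrics

Greedy confidence-ordered matching (ties by input order): each prediction
claims the unmatched truth of highest IoU if it clears the threshold, else
it is a false positive; unmatched truths are false negatives. Conventions:
P = 1 with no predictions, R = 1 with no truths; AP = 1 for zero truths and
zero predictions, 0 for zero truths with predictions. AP integrates the
all-point precision envelope by default; 101-point interpolation is offered
for COCO-style comparability (the two differ by < 0.01 on dense curves).
mAP@0.5:0.95 averages AP over IoU 0.50–0.95 in 0.05 steps; with a single
class mAP = AP. Segmentation mAP uses mask IoU by default (box IoU is
available). MAPE is reported in percent with zero-truth samples excluded
and counted, since a relative error against a zero truth is undefined.

## Cultivar screen

Per-sample ratios are averaged to one mean per cultivar-year (each berry
half is a sample; halves are not paired). One-dimensional K=2 K-means has
an exact, deterministic solution — the optimal two-cluster partition is
contiguous in sorted order — so the screen scans the n−1 sorted split
points for minimal within-cluster sum of squares instead of running
Lloyd's iteration from random starts. Two separating values are reported:
the **centroid midpoint** (the K-means decision boundary, the headline
threshold) and the **boundary midpoint** between the closest cross-cluster
members. Welch's t-test (unbiased variances, Welch–Satterthwaite df,
two-sided Student-t tail) validates the split on the mean ratios and,
independently, on the firmness covariate; with equal variances and sizes
it reduces to the pooled t-test (df = n_a + n_b − 2), which the tests
check. The ratio-vs-firmness relation is an ordinary least-squares fit
reporting slope, R² (defined 0 when SS_tot = 0), and residual RMSE.
Years with fewer than 4 cultivars are skipped; per-year screening is the
default with a pooled option, since susceptibility varies year to year.

## Cultivar simulation

`simulate_cultivars` draws a two-group population: group mean ratios 0.12
(resistant) and 0.32 (susceptible) — a separation whose midpoint, 0.22,
sits where a practical susceptibility threshold is expected to land —
with balanced group assignment (a shuffled half/half label vector, matching
the comparable cluster sizes such screens produce). Cultivar means scatter
around their group level with sd = within-sd/4 (default 0.0075), berry
ratios are truncated-normal on [0, 1] with within-sd 0.03 and 20 berries
per cultivar, and firmness is `5.0 − 10.0 · mean_ratio + N(0, 0.4)` MPa/%,
placing values in the 1.5–4 MPa/% range of a force-deformation slope index.
The between-cultivar spread is deliberately small relative to the group
separation: label recovery is meant to certify the clustering analysis, not
to hinge on lucky draws — with these defaults recovery is exact across 100
seeds. Real populations are messier (continuous susceptibility, year
effects, unbalanced groups); the simulation is a correctness harness, not a
genetic model.

## Label dialect, splitting, augmentation

Labels are one text file per image: `class cx cy w h` for boxes, `class
x1 y1 x2 y2 ...` for polygons, all normalized, 6-decimal writes (round-trip
exact to 1e-6). Predictions append a trailing confidence. Ground-truth
polygons are traced from masks by marching squares at level 0.5 (which runs
along the exact member/non-member pixel boundary) and simplified to ≤ 0.4 px
chordal deviation; re-rasterizing recovers the mask with IoU ≥ 0.98
(measured ≥ 0.999 on generated berries).

Splitting shuffles ids with a seeded generator and takes floor sizes for
validation and test with the remainder to train: 185 images at 8:1:1 give
149/18/18 deterministically.

Augmentation: flips and rotations transform polygon vertices analytically
and rebuild boxes as clipped axis-aligned hulls of their transformed
corners (boxes and polygons are independent task-specific label lists, so
boxes are rebuilt from their own corners); photometric ops (saturation,
brightness, exposure/gamma, scales drawn in [0.7, 1.3]) leave annotations
untouched. Rotations by multiples of 90° on square images go through the
lattice bijection (`rot90`), preserving mask areas exactly; arbitrary
angles keep the canvas, fill exposed pixels with the background color, and
change rasterized areas by < 3 %. "Augmented three times" is interpreted as
three augmented copies per original, with a `keep_original` toggle.

## Numerical choices and degenerate inputs

* Box/mask IoU return 0 on empty unions; IoU of identical nonempty inputs
  is exactly 1.
* Clustering of identical values, Welch with n < 2 or two zero-variance
  samples, OLS with constant x, and MAPE with all-zero truths are errors,
  not silent numbers.
* K-means split ties keep the first (smallest) split point; matching ties
  keep input order.
* All stochastic components take explicit integer seeds; there is no
  global RNG state.

## Problem sizes used in validation

The shipped checks run at desk scale on one CPU: 20 plates × 20 berries for
the classical-recovery claims, 2 plates × 6 berries for the
export/evaluate round trip, 100 simulation seeds × 20 cultivars × 20
berries for the screen, ≥ 50 random instances for the AP oracle and ≥ 20
mask pairs for the IoU oracle. These sizes were chosen so the whole suite
re-runs in well under a minute of compute per module while keeping every
estimate's sampling error far below its acceptance margin.
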
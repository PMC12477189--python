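# Methods

## Scope and data model

The package operates entirely on YOLO-format bounding boxes: one text file
per image, each line `class_id cx cy w h` in coordinates normalized to the
image dimensions, with a sixth confidence column for detector output. Four
classes are modeled: `leaf`, `petiole`, `height` (the stem structure whose
box spans the plant vertically) and `calibration` (a reference board of
known physical height standing next to the plant). The id→name map is
configurable so three-class datasets without an annotated board also load;
boxes nudged past the frame by annotation jitter are clipped with a warning
rather than rejected. Training or assembling the detector itself is out of
scope — the package consumes and evaluates its output.

## Trait computation

Scale conversion uses the board's known height of 1.0 cm: the board's pixel
height `Hs` (tallest calibration box × image pixel height) gives
`r = Hs / 1.0` pixels per centimeter, and the stem box's pixel height `Hp`
gives the plant height `PH = Hp / r`. Written with `r` in px/cm, the
division is the only dimensionally consistent reading, and it is confirmed
by exact round-trip recovery against the generator. When several stem boxes
are detected the tallest is used, mirroring the board rule. Since both
boxes scale with the image, `PH` is invariant to uniform rescaling — a
property test covers this.

Petiole–leaf association expands each petiole box by `margin_frac` (default
0.10) of its own width and height per side and assigns a leaf to a petiole
when the leaf's *center* lies inside the expanded rectangle. The center
rule is the cheapest geometry consistent with a rectangular membership
criterion; overlap-area rules are possible but not implemented. Overlap
conflicts go to the petiole with the nearest center, remaining ties to the
lower box index, making the assignment deterministic and a partial
function: assigned + unassigned = total leaves, no leaf double-counted.

Per-sample relative error is `100·|predicted − measured| / measured`,
reported to one decimal; the manual measurement is the denominator, the
only convention that reproduces every printed petiole-count error in the
published measured-vs-predicted comparison we checked against. The
corresponding printed *height* error column is not consistent with this (or
any obvious) formula and is deliberately not reproduced.

## Synthetic scenes

The generator emulates a side view of a potted plant as pure box geometry —
no rasters, since the detector is out of scope. Per scene it samples a
pixel scale uniformly in [8, 20] px/cm (so the scale conversion is
genuinely exercised), a plant height from the treatment's normal
distribution, and a petiole count from its integer range; petioles attach
alternately left/right at evenly spaced heights along the stem, each
carrying 1–3 leaves whose centers are placed inside the parent petiole box.
Treatment defaults: CK 33 ± 3 cm with 9–11 petioles, W1 27 ± 3 cm with
7–9, W2 22 ± 3 cm with 5–7. These are declared, not inferred — the source
study publishes only a 20–38 cm sample range, and the defaults are chosen
to produce the strong between-treatment effects (Cohen's d ≫ 0.8) that
motivate the traits as stress indicators.

Construction identities hold exactly: the board's pixel height equals the
sampled px/cm × 1.0 cm and the stem's equals height × px/cm, so zero-noise
extraction recovers the truth to float precision (asserted at 1e-9 cm).
Geometry guarantees unambiguous association: petiole rows are ≥1 cm apart
vertically while association rectangles extend only 0.48 cm from a petiole
midline, and leaf centers sit on the outer part of their petiole, clear of
the shared stem column — so each leaf center lies in exactly one expanded
rectangle. Scenes that cannot satisfy these constraints are resampled a
bounded number of times before erroring.

The noise model corrupts ground truth into plausible detections:
per-box dropout, leaf↔petiole label swaps (the confusion mode detectors
actually show for these classes), center/size jitter proportional to box
size, Poisson-distributed spurious boxes, and confidences drawn higher for
true boxes (U(0.55, 0.99)) than spurious ones (U(0.05, 0.5)). The default
level — jitter 0.05, drop 0.05, one spurious box per scene, confusion
0.05 — is a single declared "moderate detector" operating point. A null
spec returns the input with confidence 1. What the generator does *not*
model: occlusion, lighting, perspective, correlated detector failures, or
within-plant trait correlations; passing tests therefore demonstrate
correctness of the downstream computations under known geometry, not
detector performance on real imagery.

Cohorts derive per-scene seeds from the master seed with counter-based
spawn keys, so generation is reproducible and order-independent.

## Detection evaluation

Matching is greedy: predictions in confidence-descending order (ties by
input order) claim the unmatched same-class ground truth with the highest
IoU ≥ threshold (ties by lower index). AP uses all-points interpolation —
the precision envelope is made non-increasing and integrated over recall —
matching modern evaluator practice; a brute-force step-function oracle in
the tests checks equality on random instances. Classes absent from the
ground truth are excluded from mAP. The confusion matrix switches to
class-agnostic matching (defaults: IoU 0.45, confidence 0.25) so
misclassified-but-localized boxes land in off-diagonal cells; unmatched
ground truths and predictions go to a background column/row.

## Statistics

Univariate tests delegate to scipy: Shapiro–Wilk (3 ≤ n ≤ 5000), Levene
with mean centering by default (median centering available), Kruskal–Wallis
with tie correction, and Mann–Whitney U — exact enumeration when
`n_a·n_b ≤ 400` and the data are tie-free, otherwise the normal
approximation with tie and continuity corrections. The pairwise treatment
matrix reports raw, unadjusted p-values (the analysis it mirrors presents a
raw-p heatmap); Holm/Bonferroni can be applied downstream. Cohen's d uses
the pooled SD with (n−1) weights, no small-sample correction by default.

The Wilks'-Λ MANOVA is implemented directly: Λ = det(E)/det(E+H) from the
pooled within-group (E) and between-group (H) SSCP matrices, with Rao's F
approximation for the p-value (exact for two response variables, the case
used here); a test cross-checks Λ and p against statsmodels' MANOVA to
1e-10. Degenerate inputs (singular E, all-identical values) raise or return
the boundary result (statistic 0, p 1) explicitly.

Type-I calibration of the whole battery is asserted by simulation: 2000
null datasets per test, rejection rate at α = 0.05 required within
0.05 ± 0.02.

## Classification benchmark

Features are z-scored with statistics fitted on the training split only,
then multiplied by the weight pair — kept as *two* scaled columns rather
than collapsed to a scalar sum, because per-feature permutation importances
are part of the output and a scalar input could not produce them (a scalar
mode exists behind a flag). Splits are stratified 80/20 (stratification
guarantees every treatment appears in the test set) with a fixed default
seed; because a single 20% split of a small cohort is high-variance, a
repeated-splits mode averages accuracies over several split seeds and is
used for rank comparisons. The seven families run with their standard
hyperparameters (L2 logistic capped at 100 iterations, RBF SVM C = 1 with
scaled gamma, 100-tree Gini forest, unbounded Gini tree, k = 5 KNN,
Gaussian NB, 0.1/100/depth-3 boosting); per-cell fit failures are recorded,
not raised.

The weight sweep probes a scale-sensitivity contrast. Tree-based models
split on order statistics, so positively scaling a column cannot change
their decisions — their accuracy rows are flat across combos (up to rare
last-bit ties between candidate splits, which is why the repeated-splits
flatness assertion carries a one-test-sample tolerance while single fixed
fits are asserted exactly). Logistic regression's L2 penalty, by contrast,
makes a down-weighted column expensive to use: at weights 0.9–0.1 the
height feature is effectively suppressed and accuracy falls toward what the
petiole count alone supports. The benchmark cohort for this check is 300
scenes (100 per treatment) passed through the default detector noise and
trait extraction — the full pipeline, so the features carry realistic
measurement error; scenes whose stem or calibration box was dropped are
skipped and counted. Cohort and simulation sizes throughout (120 scenes for
recovery, 45 images for detection metrics, 2000 null replicates, 10 split
seeds) are the package's declared problem sizes, chosen for stable
statistics.

## Numeric reference operations

The detector-architecture building blocks are provided as framework-free
inference references: same-padded cross-correlation (einsum fast path,
quadruple-loop oracle in tests), adaptive-kernel convolution as a
simplex-weighted sum of convolutions with different kernel sizes, scaled
dot-product attention, non-overlapping local-window attention, and bi-level
routing attention as a simplex-weighted sum of per-group attentions. Mixing
weights that a network would learn are plain inputs constrained to the
simplex. Two interpretive choices are recorded: the attention scale divides
by √d (the standard reading of the stated normalization purpose; a
`scale="linear"` switch divides by d instead), and grids not divisible by
the window size use truncated edge windows, equivalent to masked
zero-padding. All operations are asserted equal to naive-loop oracles at
1e-12 on small random instances.

## Known limitations

- Box-level synthesis cannot surface errors that only real imagery induces
  (occlusion-driven misses, systematic localization bias).
- The height-error convention of the published comparison table could not
  be reconstructed and is not reproduced; only the petiole-count error
  column anchors the relative-error definition.
- Published end-to-end numbers that depend on the unreleased image dataset
  and trained detector (overall mAP, the 6.9%/10.12% cohort error rates,
  specific p-values, the exact accuracy grid) are covered qualitatively by
  the property suites, not reproduced numerically.
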
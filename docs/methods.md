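# Methods

This note documents the models, conventions and numerical choices behind
`seedsalt`, and what the synthetic test bed does and does not show.

## Segmentation

Binarization selects one channel of the RGB raster (`red`, `green`,
`blue`, or `grey` = the rounded mean of the three) and compares it to a
threshold: foreground iff value ≥ T for `bright_objects`, value ≤ T for
`dark_objects` (both inclusive).  An optional circular region of interest
masks everything outside the dish.  `threshold="otsu"` scans all 256
split points of the (ROI-restricted) histogram and takes the split
maximizing the between-class variance, expressed so that the polarity's
foreground rule realizes the optimal split; ties go to the smallest
threshold.

Connected components are labeled by a combined contour-tracing / region-
labeling pass: one raster scan over foreground pixels in which

* an unlabeled pixel with background above starts a new **external
  contour** — a clockwise Moore-neighborhood trace (neighbor order E, SE,
  S, SW, W, NW, N, NE; restart direction `(previous + 6) mod 8`; Jacob's
  stopping criterion) that labels every boundary pixel;
* a pixel with unvisited background below starts an **internal contour**
  around a hole, so holes never spawn new labels (visited background
  pixels are marked); a pixel can open both contours at once;
* any other unlabeled foreground pixel inherits its left neighbor's
  label.

Foreground connectivity is 8 and background 4, the standard companion of
Moore tracing.  Labels are assigned in first-encounter raster order,
which makes region numbering deterministic.  The image is padded by one
background pixel so border components trace correctly.  The labeling is
verified against an independent 8-connected flood fill
(`scipy.ndimage.label`) on hundreds of random masks.

Size gating keeps regions with `min_area ≤ area ≤ max_area` and centroid
inside the ROI, then relabels survivors consecutively.  Touching seeds
form a single region; no watershed splitting is attempted, so clumps
count as one object.

## Features

A seed is the interior of its outer contour: interior holes (glare in
back-lit images) are filled (`scipy.ndimage.binary_fill_holes`) before
any feature is computed.  Conventions:

* **Perimeter** is the polygonal length of the closed contour through
  pixel centers: axial step 1, diagonal step √2.  A one-pixel region gets
  perimeter 1.0 (one closed step) so that circularity and compactness
  remain finite and the contour-length invariant (≥ 1 step per boundary
  pixel) holds for degenerate regions.
* **Axes**: the 2×2 second central moment matrix of the pixel coordinates
  has eigenvalues λ₁ ≥ λ₂; major = 2√λ₁ and minor = 2√λ₂, which for a
  solid ellipse recover the semi-axes.  Single-row/column regions have
  λ₂ = 0, so the minor axis is floored at 0.5 px (half a pixel's extent).
  Eccentricity is major/minor (≥ 1), not the classical ellipse
  eccentricity.
* **Circularity** = perimeter²/area (4π ≈ 12.57 for an ideal disc;
  digital discs run a few percent above).  **Compactness** = area /
  perimeter.
* **Quartiles** of the grey ((R+G+B)/3) and per-channel distributions use
  linear interpolation between closest ranks (`numpy.percentile`
  default).  The grey histogram peak uses rounded integer intensities
  with ties to the smallest bin.  Whether the original portal
  interpolated quartiles or took nearest ranks is unknowable; the choice
  is documented here and used consistently, including by the synthetic
  tests.
* **Hue** follows the standard RGB→HSB conversion, degrees in [0, 360),
  with zero-saturation pixels assigned hue 0.  `hueKmax` is the most
  populated of K equal classes [360·i/K, 360·(i+1)/K), ties to the
  smallest index.

## Calibration

px/cm = measured diameter in px / known diameter in cm, kept at full
precision; the two-decimal *truncated* display mirrors how such scales
are conventionally printed (846.50 px / 8.50 cm → 99.58).  Seed length
and width are twice the major and minor semi-axes converted to mm.  All
internal arithmetic is full precision; truncation is display-only, since
compounding truncated intermediates produces irreproducible values.

## Consensus classification

Each seed inherits its plate's condition label for training.  Features
are standardized to zero mean / unit variance on the training set (the
nearest-neighbour and SVM members need comparable scales).  The 13
members are scikit-learn models, one per family of the original WEKA
ensemble; exact WEKA hyperparameters are not recoverable, so each member
uses fixed documented defaults with a shared seed:

| member | model |
|---|---|
| NaiveBayes | GaussianNB |
| MultilayerPerceptron | MLPClassifier, 1×20 hidden, 300 iter |
| SMO | SVC (RBF) |
| IBk | 1-nearest-neighbour |
| KStar | 5-NN, distance-weighted |
| LWL | 25-NN, distance-weighted |
| DecisionStump | depth-1 tree |
| HoeffdingTree | entropy tree, min 10 samples/leaf (conservative splits) |
| J48 | entropy tree, min 2 samples/leaf |
| LMT | logistic regression (degenerate one-node logistic model tree) |
| RandomForest | 100 trees |
| RandomTree | random-splitter tree, √p features |
| REPTree | entropy tree, cost-complexity pruning α = 0.01 |

The consensus rests on the ensemble mean, not on any single member's
tuning.  Members are thresholded to hard labels; the plate consensus is
the mean over algorithms of the percentage of the plate's seeds labeled
salt, and the plate is salt iff consensus > 50 (exactly 50 → non-salt).
A ZeroR majority-class baseline is available (`with_baseline=True`) but
never joins the consensus.  Attribute subsets restrict the input to all
23, the 7 morphological, or the 16 colorimetric columns.

## Evaluation

Undefined ratios (zero denominators) are reported as absent rather than
0, so a degenerate confusion table cannot masquerade as a score.
Fisher's exact test is two-sided (sidedness is a documented choice):
p sums the hypergeometric probabilities of all tables at the observed
margins that are no more probable than the observed table, with 1e-7
relative slack on the comparison to absorb floating-point ties;
degenerate margins give p = 1.  Log-gamma arithmetic keeps the
enumeration exact to ~1e-12 relative; the implementation is checked
exhaustively against `scipy.stats.fisher_exact` and against an
exact-rational enumeration.

k-fold cross-validation operates on plates, never seeds, so seeds from a
test plate can never leak into training.  Folds are stratified by
condition and shuffled by the seed; when k exceeds the smaller class's
plate count (e.g. leave-one-plate-out), stratification is infeasible and
plain shuffled folds are used.  Confusion counts are pooled over folds
and the metrics computed once (micro-averaging), matching how single
cross-validated metric values are conventionally reported.  A training
fold that loses one class is skipped with a logged warning.

## Synthetic plates

The generator emulates the study conditions: 90 seeds per plate (the
observed mean for 0.1 g of seed is ≈ 92, range 50–125), a dish of radius
425 px in a 1024² image (≈ 100 px/cm, the fluorescent-camera dish
calibration), seed semi-major axis ~N(9.8, 1.2) px with aspect ratio
~N(1.9, 0.15) (the observed fluorescent-mode axis means are 9.76 and
5.17 px).  Seeds are non-overlapping filled ellipses, uniform orientation
in [0, π), placed by rejection sampling with bounded retries (overlap
behavior of real clumps is deliberately not modeled).  Color regimes per
mode: FLUO — background (8, 6, 4), seed mean (150, 60, 5) (red-dominant,
near-zero blue); VISBACK — background 230 grey, dark brownish seeds;
VISFRONT — background 120 grey, darker textured seeds (extra in-seed
noise, σ = 8).  Per-seed channel means are drawn with σ ≈ 10–12 and the
whole image gets pixel noise σ = 6, clipped to [0, 255].  The default
salt effect is a ×1.3 semi-major mean and +40 red mean — documented
package constants representing a strong fluorescent response, chosen once
so the one-training-plate regime is separable.

What passing synthetic tests show: the pipeline's algorithms are correct
and self-consistent (segmentation recovers the generated seeds with IoU
≥ 0.9, features recover the generating parameters within 5–10 %, the
consensus classifier detects the programmed effect and stays at chance
without it).  What they do not show: performance on real plates, which
face touching seeds, uneven illumination, dish-rim artifacts, batch
effects between growing seasons, and subtler effect sizes.  Real-image
metric values cannot be recomputed here and are only reproduced from
their published confusion counts.

## Numerical and interface choices

* Detection setups are versioned JSON; unknown keys are rejected so typos
  fail loudly.  Presets (FLUO red ≥ 60, VISBACK grey ≤ 150, VISFRONT
  grey ≤ 95, area gate 20–2000 px) are package defaults — the original
  portal's values were never published.
* 16-bit rasters are rescaled to 8-bit by floor(v/257): deterministic and
  documented, at the cost of half-LSB bias.
* Feature CSVs print floats at 6 decimals (beyond any display precision
  used downstream); roundtrips are lossless at that precision.
* Metric displays: helpers for both half-up rounding and truncation are
  provided, because published two-decimal values mix both conventions;
  comparisons against printed values accept either.
* Problem sizes in the test suite and acceptance script (40 test plates
  for the effect and null runs, 40 plates for cross-validation, 512²
  plates in fast unit tests) are chosen to give tight binomial intervals
  while keeping a full run in a few minutes on one core.

## Known limitations

Touching seeds count as one region.  The ROI is user-supplied, not
auto-detected.  Only the hue channel of HSB feeds the color classes —
saturation/brightness histograms are out of scope.  The ensemble's member
hyperparameters are fixed, not searched.  The generator does not model
seed texture, specular glare or plate-rim artifacts.
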
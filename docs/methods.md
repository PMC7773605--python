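# Methods

`xmiconnect` implements a joint-classification functional-connectomics
pipeline: regional time series are converted into cross-mutual-information
(XMI) connectivity vectors, a dual-output multilayer perceptron classifies
each vector simultaneously by clinical diagnosis (ADHD vs. Control) and by
Iowa Gambling Task (IGT) performance class (low vs. high), and summed path
weights identify the connections that drive both decisions.  This note
records the models, the defaults and why, the numerical choices, and what
the synthetic benchmark does and does not establish.

## Connectivity estimation

**Preprocessing.** Each region's time series is linearly detrended, z-scored
(mean 0, SD 1), and clipped at |z| > `clip_z`.  The clip threshold defaults
to 3.0 SD — a conventional outlier bound for normalized BOLD-like signals —
and is configurable.  A region that is constant after detrending cannot be
normalized and is reported as degenerate by index rather than silently
dropped.

**Connection-of-interest (COI) screening.** Pearson correlations are cheap
and admit significance reasoning, so they serve as a first-pass filter
before the more expensive, threshold-free XMI statistic: per run matrix the
`ceil(top_frac * n_pairs)` largest upper-triangle correlations are marked
(`top_frac` = 0.05), and pairs marked in at least `min_prop` = 30% of all
run matrices become COIs.  Requiring recurrence across runs — but not
uniformity — keeps connections that are strong in some runs and groups only,
which is exactly where group differences can live.  Ranking uses signed
correlations by default (the largest values); an absolute-value mode is
provided since either reading of "top correlations" is defensible.  The COI
list in lexicographic (i, j) order fixes the feature order of every
downstream vector.

**XMI.** For series x, y the statistic is

    M = Σ_{k,l : P(k,l)>0} P(k,l) · ln[ P(k,l) / (P(k) P(l)) ],

normalized by ln(Nc·Nr), its maximum on an Nc × Nr grid, so values lie in
[0, 1].  Bin counts come per axis from Scott's normal-reference rule,
round((max − min)/(3.5 · s · n^(−1/3))), floored at 2 — appropriate because
preprocessed connectivity inputs are approximately normal.  The joint
density is the 2-D histogram convolved (FFT) with an isotropic Gaussian
kernel.  The kernel bandwidth is 1 grid cell per axis by default: enough to
suppress the sawtooth sensitivity of raw histograms at these sample sizes
(~154 timepoints → ~8 bins per axis), while preserving the monotone
response to dependence strength.  Setting the bandwidth to 0 recovers the
plain plug-in histogram estimator exactly; that mode is kept as an
independent oracle in the test suite, which also checks the estimator
against the bivariate-Gaussian closed form −½·ln(1−ρ²) (the plug-in
estimator carries the usual upward counting bias of order K/(2n) for K
occupied cells, and the smoothed estimator a modest downward smoothing
bias; both order correctly in ρ).  Numerical details: natural logs
throughout (the base cancels in the normalized statistic); zero-probability
cells are excluded from the sum; negative density mass from FFT round-off
is clamped to zero before renormalization; Nc is taken from the first
argument and Nr from the second, with COI pairs always ordered (lower ROI,
higher ROI) so the statistic is reproducible — under that convention
xmi(x, y) = xmi(y, x) exactly.

## Classifier

The model is a feedforward network: input features → four densely connected
hidden layers of 12 rectified linear units, each batch-normalized, → one or
two logistic-sigmoid outputs trained to minimize squared error against 0/1
targets.  (Three hidden layers are equally supported via `hidden_layers`;
four is the default.)  With two outputs, shared hidden weights force the
12-dimensional internal representation to serve *both* classifications, so
training concentrates on connections informative for diagnosis and IGT
class jointly; the categories are near-orthogonal by design, so neither
label leaks into the other.

Training protocol:

* **Under-sampling.** The majority diagnosis class is under-sampled at the
  vector level (not participant level) so the balanced set fixes chance
  accuracy at 0.5; each batch of models draws a fresh majority subset.
* **Input-feature dropout** with probability 0.4, resampled at every
  presentation — data augmentation that suppresses idiosyncratically
  predictive features.  This is input dropout, not hidden-unit dropout.
* **Stratified k-fold cross-validation** on the joint
  (diagnosis × IGT class) label, k = 5, with each sample in exactly one
  validation fold and per-fold class proportions matched within one sample.
  The whole procedure repeats over 6 independent batches → 30 models, giving
  distributional statistics of validation accuracy.
* **Optimizer.** Adaptive-moment gradient descent (rate 1e-3), 200 epochs,
  minibatches of 16, squared-error loss; variance-scaled (He) weight
  initialization; batch-norm inference uses exponentially averaged running
  statistics (momentum 0.9).  These optimizer settings are this package's
  recorded defaults — reasonable for squared-error training at this scale —
  and are all configurable and logged.

Outputs below 0.5 classify as category 0; 0.5 and above as category 1.

## Interpretation

A feature's influence on an output is its **summed path weight**: the sum
over all input→output routes of the product of traversed weights, i.e. the
corresponding entry of the product of the dense weight matrices.  Biases
and batch-norm parameters are excluded — they shift and rescale
activations but do not route input influence along paths, and the
dense-matrix product is the defined statistic.  Per
output, weights are averaged across the 30 models and z-scored across
features (sample-SD convention).  Sign semantics follow the output coding:
with ADHD → 0, strongly negative clinical Z marks connections whose strong
connectivity predicts ADHD (hyperconnectivity profile), strongly positive Z
marks Control-predictive connections.

* **Reduced feature set**: features in the ±`tail` (default 0.025)
  quantile tails of the across-feature distribution of mean clinical path
  weight.  Ties at the quantile boundary are included; ordering is by
  feature index.  The tails are taken of across-model means (mean →
  normalize → tails), the reading consistent with the normalization step.
* **Predictive connections**: |Z| > 1.65 (95th percentile of the standard
  normal) on either output; **highly predictive**: |Z_clinical · Z_igt| >
  1.65², i.e. extreme for both classifications jointly.  The rule is
  applied to unrounded Z values.
* **Targeted-vs-random comparison**: because parametric thresholds on
  network weights rest on shaky distributional assumptions, models trained
  on the targeted features alone are compared with models trained on
  equal-size random draws from a feature pool (10 repetitions of stratified
  10-fold per condition; independent-samples t-test per output,
  df = 2·10 − 2 = 18).

## Evaluation

Control (= 1) is the positive class.  HIT = TP/(TP+FN),
FAR = FP/(FP+TN), d′ = Φ⁻¹(HIT) − Φ⁻¹(FAR) (equivalently the right-tail
z-score convention z(FAR) − z(HIT) with z(p) = −Φ⁻¹(p)).  Rates of exactly
0 or 1 are nudged by 1/(2N) before the quantile transform so d′ stays
finite.  Per-model validation accuracies are tested against chance 0.5 with
one-sample right-tailed t-tests, Holm-corrected across the family of
reported outputs.  Participant-level accuracy uses the modal classification
across a participant's runs; ties (possible with an even run count) resolve
by the mean sigmoid output thresholded at 0.5.  A linear soft-margin SVM
baseline is trained *independently per output* with the same under-sampling
and fold machinery — a single hyperplane cannot make simultaneous decisions
about two orthogonal categories, which is precisely the contrast the
baseline exists to expose.

## Synthetic cohorts

Real archival fMRI of this design is access-restricted, so the package
ships a generator that emulates the study dimensions (default 80
participants, 25 control / 55 ADHD, 4 runs, 302 ROIs, 154 timepoints) and
the statistical structure the pipeline targets, without any imaging
physics.  Each region is a unit-variance mixture

    region = √(1 − c_g² − Σ c_p²) · noise + c_g · global + Σ c_p · latent_p

plus independent measurement noise of SD `noise_sd` (default 0.5).  Two
regions sharing a latent with coefficient c correlate at c² before
measurement noise, so dependency strength is analytically known.  Three
pair types exist:

* **Planted clinical pairs** — coupling `coupling_strong` (0.8) for one
  diagnosis group, `coupling_weak` (0.3) for the other; the direction is
  configurable per pair so both ADHD-hyper- and hypoconnectivity profiles
  can be planted (defaults alternate).
* **Planted IGT pairs** — analogous by IGT class; they may overlap the
  clinical pairs.  An overlapping pair's two latents are scaled by 1/√2 so
  its regions stay within the unit-variance budget; when both conditions
  are "strong" its correlation equals the single-label c².
* **Background pairs** (default 40, coupling 0.55) — label-independent
  stable connections.  These mirror real connectomes, where most
  connections of interest are strong but non-diagnostic, and they give the
  COI filter a non-trivial pool: pure-noise pairs essentially never recur
  in 30% of run matrices, so without background pairs the COI set would
  collapse onto the planted pairs and the targeted-vs-random comparison
  would have no pool to draw from.

Labels: diagnosis is assigned randomly at the specified control count; a
target IGT class is assigned stratified within each diagnosis group (the
crossing that makes the labels near-orthogonal); IGT scores are then drawn
from two overlapping normals (means ±10, SD 8 — a plausible spread for a
net advantageous-minus-disadvantageous card score) and the final IGT class
is recomputed as the median split of the realized scores (ties at the
median go low), so the class/score invariant holds exactly while the few
near-median flips keep |corr(diagnosis, IGT class)| small.  All randomness
derives from the spec seed through a `SeedSequence` spawn tree; cohorts are
bit-reproducible.

What the generator does **not** emulate: hemodynamics, autocorrelated BOLD
spectra, head motion, spatial structure, site effects, or realistic
effect-size distributions.  Passing the recovery benchmarks therefore shows
the *pipeline* is correct and sensitive under known ground truth — not that
real data would yield comparable accuracy.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` run a scaled planted cohort —
40 participants (15 control), 4 runs, 30 ROIs, 154 timepoints, 12
background pairs, coupling contrast 0.8 vs 0.3 — chosen so the full
analysis (6×5 cross-validated models, a 10-shuffle permutation null, and
the 2×10×10-fold targeted-vs-random comparison) completes in a few minutes
on one CPU while the planted contrast remains comfortably recoverable.  On
this cohort validation accuracy is at ceiling for both outputs, the 5%
path-weight tails recover planted clinical pairs with precision 1.0, and
the targeted-vs-random contrast is decisive (t ≫ 0 at df 18).

The label-permutation null shuffles tags at the *vector* level,
independently per output.  Participant-level joint permutation is not used
for the null: on a perfectly separable cohort the classifier can exploit
the residual agreement of order 1/√n_participants between permuted and
true labels, inflating the null mean (≈0.56 at n = 40) for reasons
unrelated to pipeline leakage; vector-level shuffling breaks the
feature-label association completely (null mean ≈0.5).

## Known limitations

* The MLP is plain NumPy: adequate at benchmark scale, not tuned for
  thousands of input features; no GPU path.
* No parametric significance test for XMI values exists; selection relies
  on the correlation screen and the permutation-style comparisons.
* Scott's rule assumes approximate normality; heavy-tailed inputs would
  need a different binning rule.
* The SVM baseline uses scikit-learn's `LinearSVC` defaults aside from the
  iteration cap; it is a reference point, not a tuned competitor.
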
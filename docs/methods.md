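# Methods

This note records the statistical procedures implemented in `circuc`, the
choices made where the standard descriptions leave room, and what the
synthetic-data tests do and do not demonstrate.

## Preprocessing

Probe intensities are processed in a fixed order: GC-matched background
subtraction on the linear scale, clamping at 0, a `log2(x + 16)` transform,
quantile normalization, median summarization per feature, and
technical-replicate averaging (arithmetic mean of log2 values).

* **Background.** For each sample and GC-count class, the background is the
  median (configurable: mean) of the anti-genomic control probes in that
  class. A GC class without anti-genomic probes is a hard error.
* **Quantile normalization** runs on log2 probe values, separately within
  each blood fraction, because each fraction is analyzed as an independent
  cohort. The scale is a choice — the vendor chain does not document it —
  and log2 was picked for robustness to heavy right tails. Ties receive the
  mean of the reference values at their tied ranks (mid-ranks with linear
  interpolation), which makes the map deterministic and row-order
  invariant; the transform is idempotent to ~1e-15.
* The `+16` offset keeps zero-intensity probes finite (`log2 16 = 4`) and
  compresses low-intensity noise.

## SAM (two-class, unpaired)

Score: `d_i = (x̄_case − x̄_control) / (s_i + s0)` with `s_i` the pooled
standard error. The fudge factor `s0` is tuned over the percentiles
{0, 5, …, 95} of the `s_i` distribution, minimizing the coefficient of
variation of window-wise median absolute deviations of `d` across 100
`s_i`-quantile windows (ties go to the smallest percentile); a fixed `s0`
can be supplied instead.

The null is built from distinct case/control label assignments: all of
them when the space is no larger than `n_permutations` (exact null, e.g.
C(8,4)=70 in small tests), otherwise a uniform sample without replacement
(20 v 20 has ~1.4e11 assignments). For a threshold `delta`, calling cut
points are placed at the first ordered score whose departure from the
permutation-expected order statistic reaches `delta` (separately above and
below the zero crossing); estimated FDR is
`pi0 · median_perms(#scores beyond cuts) / #called`, with `pi0` estimated
from the fraction of permuted scores inside the observed interquartile
range. The smallest `delta` on a grid of observed departures (capped at
512 points) achieving the target FDR defines the call set; q-values are the
smallest estimated FDR at which a feature is called. Features whose
statistic exceeds every permuted score receive q = 0 and are flagged: this
is a floor imposed by permutation granularity, not a true zero.

Calibration behaviour worth knowing: on planted data the empirical
false-call fraction sits at ~1 % for a nominal 1 % target, but on pure-null
data the procedure calls its single most extreme feature in roughly half
of runs — whenever the observed extreme beats the median permuted extreme,
an exchangeability coin flip inherent to the median-false-count estimator
at very small call counts.

## Consensus selection

100 iterations; each draws 18 of 20 cases and 18 of 20 controls *without*
replacement (subsampling, not bootstrap), runs SAM at FDR 1 % with 200
permutations, and tallies calls. Features with frequency ≥ 0.9 are
selected (the comparator is configurable to strict `>`). Direction is
recorded per feature and flagged `mixed` if a feature is ever called in
both directions. Candidate subsets are drawn from sample ids in sorted
order, so frequencies are invariant to input column order.

## Nested cross-validated evaluation

Each of 100 repetitions draws 18 + 18 training samples; the remaining
2 + 2 are the test set. Feature selection happens strictly inside the
training cohort: the consensus selector runs on 16 + 16 inner subsamples
for 20 iterations (the inner iteration count is not documented in the
original protocol; 20 keeps the procedure inside a practical runtime and
the paper-style 100 is available by config at ~5× cost) with SAM at
FDR 1 % and 100 permutations. Selected features are standardized by
training-set mean/sd and fed to a soft-margin SVM with RBF kernel,
`gamma = 1/#features` and `C = 1` (the e1071/libsvm defaults the original
analysis relied on); standardization is on by default and switchable.
If the inner consensus selects nothing, a single SAM pass on the full
training split is used; if that is also empty the repetition predicts the
training majority class (control on ties) and is logged. Confusion counts
are aggregated over repetitions; all performance measures derive from the
aggregate. The protocol is Monte-Carlo splitting (repeated random 18:2
splits), which is what the underlying study describes operationally even
though it labels the scheme k-fold.

## Correlation clusters

Pearson correlations are computed over all samples, cases and controls
pooled. Features are clustered with complete linkage on distance `1 − r`;
candidate clusters are the dendrogram subtrees, largest first: subtrees
already satisfying *minimum* pairwise `r > 0.6` are accepted whole, then
leftover features are claimed by trimming remaining subtrees (dropping the
member with the lowest mean correlation to the rest until the minimum
criterion holds). The naive alternative — cutting the tree at height
`1 − 0.6` — splits genuine ρ = 0.75 blocks whose empirical complete-linkage
height wobbles above the cut, and was rejected for that reason. Pairwise
p-values use the t transform `t = r·sqrt(n−2)/sqrt(1−r²)` with `n−2`
degrees of freedom. Zero-variance features are reported as unassigned.

## Enrichment and qPCR

* One-sided Fisher tests are hypergeometric upper tails; binomial tails are
  exact upper sums; term enrichment is a hypergeometric over-representation
  test with a Benjamini–Hochberg column reported but not used for filtering
  (ranking is by raw p).
* The target down-regulation test runs SAM on the mRNA matrix at FDR 0.1 %,
  keeps calls with fold change ≤ 1/2 (the `fold change > 2` filter is read
  symmetrically), and contrasts targets vs non-targets; the binomial null
  probability is the non-target down-regulation rate.
* qPCR: ΔCt subtracts the arithmetic mean normalizer Ct per (group,
  replicate) — four normalizer assays, no aggregation rule documented, and
  mean-Ct is the dominant convention. Fold change is the ratio of mean
  `2^(−ΔCt)` values; the test is pooled-variance Student (Welch by flag).
  Cross-platform concordance is a paired t-test on log2 fold changes, so
  up- and down-regulation are symmetric.

## Synthetic data

The generator emulates a 20-case/20-control cohort over 847 features on a
log2 scale: baselines uniform in [4, 14] (the observed intensity range of
such arrays), 31 planted up-regulated features with log2 fold changes
uniform in [0.5, 1.0] (linear 1.4–2.0, the range the validated biomarkers
showed), per-feature Gaussian noise with sd 0.5, and four latent-factor
correlation blocks (sizes 8, 8, 6, 6) at pairwise r = 0.75 placed on the
planted features, mirroring the observation that most of a real biomarker
panel falls into a few tightly correlated clusters. A block with target
correlation ρ mixes a shared standard-normal factor with loading √ρ and
idiosyncratic noise with sd √(1−ρ), giving exact pairwise correlation ρ in
expectation.

The probe layer (4 probes per feature; per-probe affinity offsets
N(0, 0.25²) in log2 units; additive linear background `40 + 8·(gc − 6)` for
GC counts 6–14; 20 anti-genomic probes per GC class; linear probe noise
sd 5) is sized so that affinity offsets are removable by median
summarization and the background is removable by GC correction.

What the synthetic data does **not** emulate: probe sequence effects,
scanner saturation, batch structure, heavy-tailed or intensity-dependent
noise, and realistic miRNA–target network topology. Passing tests
demonstrate the statistical machinery is correct and calibrated under the
stated model, not that the biological conclusions of any particular study
are reproduced.

## Problem sizes used by tests and the acceptance script

SAM null/planted calibration: 20 runs × 200 permutations at full scale
(847 × 40). Consensus: 100 iterations × 200 permutations per run; 20 runs
in the test suite, 5 in the acceptance script. Nested evaluation: 100
repetitions (planted); label-permutation control: 8–12 permuted cohorts ×
15 repetitions. Cluster recovery: 20 runs of 40 features × 40 samples.
These sizes put the full suite at a few minutes on one CPU.

## Known limitations

* Under the default planted conditions, features with log2 fold change
  near 0.5 have per-subsample call probabilities well below the ~0.95
  needed to reach 90 % selection frequency, so consensus recovery of the
  planted panel averages ~75 %, with the remainder being genuinely
  marginal effects. This is a property of the stated conditions, not of
  the selector: the same SAM configuration out-calls a BH-corrected
  t-test on identical data.
* SAM's FDR estimate is unstable when fewer than ~10 features are called
  (integer granularity of the median false-call count); q = 0 values are
  flagged for this reason.
* The Monte-Carlo split evaluation yields slightly optimistic variance
  estimates relative to true k-fold schemes because test sets overlap
  across repetitions; the aggregate point estimates are unaffected.
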
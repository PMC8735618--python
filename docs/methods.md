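# Methods

## Model

OPLS-DA is PLS1 regression of a ±1 class code on the feature matrix, after
filtering out X-variation orthogonal to the class contrast. For column-
centered (and scaled) X and encoded y:

* predictive weight: w ∝ Xᵀy, ‖w‖ = 1 (single-response NIPALS converges in
  one pass; the iterative loop with tolerance 1e-12 / 500 iterations is
  retained for a multi-response extension);
* orthogonal components, repeated `k_ortho` times on the running deflation:
  t = Xw, p = Xᵀt/tᵀt, w_o ∝ p − (wᵀp)w, t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o,
  X ← X − t_o p_oᵀ;
* final predictive component on the deflated X: t = Xw, c = yᵀt/tᵀt,
  ŷ = c·t.

Predictions of a (1 + k)-component OPLS model are mathematically identical
to those of a (k + 1)-component PLS model; the test suite asserts this
against an independent NIPALS PLS implementation. What OPLS buys is an
interpretable score axis: all between-class difference is concentrated on
t, which is what the ROC/Youden step thresholds.

**Class encoding.** The positive class maps to +1, the other to −1, and y
is *not* re-centered by the sample mean: with the symmetric codes the
midpoint between classes sits at ŷ = 0 regardless of imbalance, so
"predict positive iff ŷ ≥ 0" and the score-axis threshold stay meaningful.
Ties at exactly 0 resolve to the positive class.

**Metrics.** R²X is the captured fraction of the X sum of squares (per
component, stored separately for the predictive and each orthogonal
component); R²Y = 1 − RSS/TSS of the encoded y; Q² = 1 − PRESS/TSS under
7-fold venetian-blind cross-validation inside the training set (distinct
from the external validation). VIP over the single predictive component is
VIP_j = √p·|w_j|, so the squared scores average to exactly 1; features with
VIP > 1.5 are reported as discriminatory, following the usual convention.

**Degenerate inputs.** If Xᵀy is numerically zero (e.g. a constant X after
scaling), the model is flagged degenerate, scores are 0 and every subject
is assigned the positive class — under matched classes this yields exactly
50% held-out accuracy, which is the correct "no information" answer.
Orthogonal extraction stops early when the deflated X falls below 1e-10 of
its original sum of squares or the orthogonal weight vanishes. Requesting
more components than rank(X) − 1 is an error.

`k_ortho` defaults to 1 and can be chosen by maximizing internal Q² up to a
cap of 5 (`select_k_ortho`); the component count is deliberately exposed as
configuration rather than hard-coded, since the right value depends on how
much structured off-contrast variation the data carry.

## Validation design

Each of the 100 repetitions: (1) if classes are unequal, subsample the
majority class to the minority size — re-drawn every repetition so the
estimate averages over exclusion noise; (2) split each class into 10
stratified folds (seeded within-class shuffle, round-robin deal from fold
0, so per-fold class counts stay balanced and a constant classifier scores
exactly 50%); (3) per fold, estimate centers/scales on the training folds
only, fit OPLS-DA, and score the held-out fold through the same scaler — a
test asserts that editing test-fold values changes training statistics by
exactly zero. Accuracy is (TP+TN)/n per fold, averaged fold → repetition →
overall; sensitivity is defined on the positive (recent-depression) class.
The 95% CI of the mean accuracy is the normal-approximation interval over
the 100 repetition means — deliberately an uncertainty of the *procedure
mean*, which is why it is much narrower than a per-subject binomial
interval would be.

The permutation null re-runs the identical machinery with labels permuted
uniformly once per repetition (the permutation is re-drawn along with the
subsample, since the matched-subsample composition is part of the noise
being averaged over). Real and null per-repetition means are compared with
a two-sided two-sample KS test, exact when both samples have ≤ 25 values
and asymptotic otherwise.

**A calibration caveat, honestly stated.** Under a true null the *marginal*
distributions of real and null repetition means coincide, but the real
repetitions share one fixed labeling and are therefore correlated: their
empirical distribution concentrates at that labeling's conditional
accuracy, while the null samples the marginal. The KS comparison of a
conditional against a marginal distribution is anti-conservative even with
no signal (measured here: p > 0.05 in only ~62% of zero-effect runs rather
than the nominal ≥ 95%). KS p-values from this design are evidence of
*gross* separation, not calibrated type-I error rates; the decisive
separations reported for real effects (D ≈ 0.9, p < 10⁻⁴⁰) are far outside
this gray zone.

## Synthetic cohorts

The generator's defaults are the study conditions: 81 recent / 30 lifetime
/ 107 none; group-specific age (55/65/61 y means) and female fraction
(46.9/63.3/38.3%); clinical-chemistry baselines at clinically typical
values (e.g. triglycerides 1.7 ± 0.95 mmol/L, HDL 1.1 ± 0.30 mmol/L);
antidepressant/statin/fibrate use probabilities per group, with
antidepressant use structurally absent in the never-depressed group.
Spectra are sums of Lorentzian resonances (Gaussian optional) on a
0–5.5 ppm axis at 0.001 ppm steps — lipoprotein methyls at 0.84/0.895 ppm,
methylenes at 1.27/1.385 ppm, GlycA at 2.045 ppm, glutamine at 2.45 ppm,
plus non-informative peaks and a residual-water hump inside the excluded
4.5–5.0 ppm window — with i.i.d. Gaussian point noise (sd = 2% of the
median peak amplitude) and 18% between-subject amplitude variation.

Injected group differences are standardized mean shifts (Cohen's d, recent
vs rest) applied simultaneously to a clinical variable and to the
same-named resonance amplitude. Defaults (+0.45 on the triglyceride/VLDL
resonances and serum triglycerides, +0.35 GlycA, −0.35 HDL and glutamine,
−0.30 HDL cholesterol) were chosen once to land cross-validated accuracy
in the moderately-separable 55–75% band (measured: ~61–66% across seeds);
a per-subject latent lipid factor (coupling 0.6) correlates serum
triglycerides with the CH₂ resonances as in real serum. One master seed
drives per-component substreams, so identical configs are bit-identical.

What the simulation does **not** emulate: peak-position jitter and overlap
misassignment, baseline/phase artifacts, non-Gaussian clinical
distributions (ferritin, ALT are strongly skewed in practice), informative
missingness, and any within-cohort covariance structure beyond the single
lipid factor. Passing tests therefore demonstrate that the machinery
recovers signals of known size under clean conditions — not that real
cohorts of this size will yield these accuracies.

## Numerical and design choices

* Bins are half-open [lo, hi) ppm windows; values are integrals of the
  linear interpolant of the spectrum, so adjacent bins (1.22–1.32,
  1.34–1.43) never double-count and splitting a bin is exactly additive.
  Descending ppm axes are accepted and reindexed ascending.
* Default normalization is total-area outside a 4.5–5.0 ppm water
  exclusion window; PQN (median quotient against the median reference
  spectrum) is available for dilution-dominated data. Default scaling is
  unit variance — clinical and NMR features live on incommensurate scales
  and VIP comparability assumes comparable variance; Pareto is offered.
  Zero-variance columns are dropped with a logged warning.
* Missing clinical values: default drop-subject (complete-case), median
  imputation opt-in.
* Youden ties are broken by higher accuracy, then by the smaller
  threshold; the threshold rule is score ≥ t → positive, and the reported
  threshold accuracy is computed on all data for the all-data model — an
  in-sample figure by construction.
* AUC confidence intervals use DeLong's method by default (seeded
  stratified bootstrap optional).
* ROUT is specialized from robust regression to the location model: the
  center minimizes Lorentzian loss Σ log(1 + r²/RSDR²) with
  RSDR = P68.27(|r|)·N/(N−K) refined alternately; residuals are then
  tested largest-first with |r|/RSDR against t(N−1) at step-down FDR
  levels α_i = (Q/100)·i/N. At Q = 0.1% this flags anything in clean
  normal samples (n = 100) in ~0.1% of runs and always catches a
  100-sigma point.
* Bonferroni m defaults to the number of a-priori key variables actually
  tested (the discriminatory-bin set), not the full feature count.
* The pipeline report contains no timestamps, so reruns with the same
  config and seed are byte-identical; run metadata (seed, package version,
  schema version) is embedded in the JSON.

## Problem sizes used in the checks

Simulation-backed checks run at the full 218-subject design where the
claim concerns the study conditions (null calibration, power monotonicity,
the acceptance script) and at reduced sizes (30/10/30 subjects, 0.002 ppm
steps, 2–20 repetitions) where the claim is algebraic or statistical and
does not depend on cohort scale. The acceptance script runs both group
contrasts at the full design with the default 10 × 100 validation.

## Known limitations

* Binary contrasts only; the three-level group label is always collapsed.
* One predictive component (standard for binary OPLS-DA); no O2PLS or
  kernel variants.
* The KS-vs-null comparison inherits the calibration caveat above; a
  rank-based empirical p (fraction of null runs beating the real mean)
  would be calibrated but is not what this design specifies.
* ROUT here is the location-model specialization; it is not a general
  robust-regression outlier screen.
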
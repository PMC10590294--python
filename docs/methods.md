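# Methods

This note documents the statistical model behind `immunomark`, the
choices made where the design was genuinely open, what the synthetic
cohorts do and do not emulate, and the package's known limitations.

## The classifier

The biomarker is a logistic regression of disease control (non-progression
under anti-PD-1 monotherapy: CR/PR/SD vs PD) on a small subset of immune
expression features. For a feature subset S with standardized values
z_i and coefficients w, the model is

    P(non-progression | x_i) = sigmoid(b + Σ_{j∈S} w_j z_ij)

fit by maximizing the L2-penalized log-likelihood ℓ(w, b) − ‖w‖²/(2C).
C is the *inverse* penalty strength (larger C = weaker penalty), the
convention used by most regularized-logistic implementations; the
intercept is unpenalized. The grid is C ∈ {2^k : k = −10 … 6}, seventeen
log2-spaced values spanning roughly 10⁻³–10². The phrase "log2 values
between 10⁻³ and 10²" admits more than one reading; log2 spacing across
exactly that range is the interpretation adopted here.

Standardization always uses training-portion statistics only (per CV
fold, per bootstrap resample), so no information leaks from evaluation
samples into the fit. Zero-variance columns pass through unscaled.

### Forward selection

Candidates are grown greedily: at each step the feature maximizing the
stratified 5-fold CV AUC of the augmented set enters, ties resolved by
panel order (first listed wins). Selection stops at k_max = 10 features
or when the best achievable improvement is < 0.001 AUC. Every prefix of
every per-C path is retained as a candidate, so the dual-criterion
selector can prefer a shorter model. The stopping constants are pragmatic
defaults — they keep models small and runs reproducible; the selection
literature offers no canonical values. Scoring candidates by an inner CV
(rather than by full bootstrap-OOB AUC per candidate) keeps the search
tractable; the final model's headline AUC is recomputed by the OOB
ensemble, which is the number that matters.

### Analytic variability (4·std)

Technical replicates (by default 6 biological samples × 9 replicates,
mirroring a 54-sample reproducibility study) are scored with the *fixed*
candidate model (probability × 100). Scores are mean-centered within
biological sample, pooled, and the metric is four times the pooled sample
SD (ddof = 1). Centering removes the biological signal so the metric
isolates assay noise; the factor 4 makes the bound "4·std ≤ 20" a
±10-point band on the 0–100 score scale at 2 SD each side. Singleton
biological groups contribute a centered value of 0; if *all* groups are
singletons the SD is undefined and the computation refuses.

### Final model choice

Among candidates with CV AUC ≥ 0.76 and 4·std ≤ 20, the selector returns
the maximum-AUC model, breaking ties toward smaller variability, then
fewer features, then smaller C (the more regularized, more reproducible
model). If nothing is feasible the error lists the AUC/variability Pareto
front rather than silently relaxing a bound.

## The out-of-bag ensemble score

With the feature set fixed, the cohort of n patients is resampled with
replacement B = 1000 times. Each resample refits the logistic coefficients
(and standardization constants); patients absent from the resample are
scored by that model, and a patient's final score is 100 × the mean of
their out-of-bag probabilities. A patient is out of bag with probability
(1 − 1/n)ⁿ ≈ e⁻¹ per iteration, so each patient's score averages ≈ 0.37·B
model evaluations; at B = 1000 the chance of any patient never being out
of bag is astronomically small. Resamples containing a single outcome
class cannot be fit and are redrawn (counted and logged), keeping exactly
B contributing iterations. A single named RNG seeded once drives all
draws, so scores are bitwise reproducible given (seed, B, input order).

Classification uses the cohort median score as threshold: score strictly
above ⇒ predicted non-progressor, at or below ⇒ predicted progressor.
Sending the tie to the progressor side means an odd cohort with distinct
scores yields ⌈n/2⌉ predicted progressors — with 103 patients, a 52/51
split, matching how a median-threshold rule behaves in a cohort of that
size. Quartiles are contiguous rank groups of size ⌈n/4⌉/⌊n/4⌋ with the
larger groups at the low-score end (103 → 26/26/26/25).

### Known bias of the pooled OOB AUC at the null

The package's null-calibration suite measures a real and easily
overlooked property: when features carry *no* signal, the pooled OOB AUC
is systematically **below** 0.5 (measured ≈ 0.42–0.45 across 1–10
features, C ∈ {0.1, 1, 10}, B up to 300). The mechanism: conditioned on
patient i being out of bag, the training resample is drawn from the other
n − 1 patients, so its class ratio anti-correlates with y_i; the refit,
unpenalized intercept tracks that ratio, depressing the scores of
held-out class-1 patients and inflating those of class-0 patients. Any
method that refits per resample and pools predictions across patients
inherits this pessimism (cross-validated AUC with pooled folds behaves
the same way). Consequences: (a) a chance-level signal shows up as OOB
AUC noticeably *below* 0.5, not at it; (b) OOB AUC estimates of a real
signal are mildly conservative. The effect shrinks as genuine signal
dominates the intercept wobble.

## Evaluation suite

- Positive class is **non-progressor** (disease control) everywhere.
- The 11 diagnostic metrics use their standard definitions; zero
  denominators yield flagged NaNs, never exceptions. Exact identities
  (FNR = 1 − sens, DOR = TP·TN/(FP·FN)) hold at full precision.
- Display rounding is half-up — 2 decimals for metrics, whole percent
  for rates — because printed clinical tables round half-up, and the
  reconstruction utility must invert exactly that rule.
- `reconstruct_confusion` exhaustively searches all integer
  (TP, FP, FN, TN) summing to n whose prevalence/sensitivity/specificity
  round to the printed values, returning the unique solution or an
  explicit no-solution/ambiguity error listing candidates. This turns a
  rounded published table into exact integer tests.
- ROC/AUC is the Mann–Whitney statistic with ties counted ½, computed
  from ranks; the curve enumerates every distinct threshold.
- Fisher tests are two-sided exact hypergeometric. Quartile-vs-complement
  DCR tests are reported unadjusted (per-quartile stars at
  0.05/0.01/0.001), matching the convention of reporting each quartile's
  own contrast.
- Comparing two predictors' sensitivities (or specificities) uses an
  *unpaired* Fisher test on correct/incorrect counts among actual
  positives (negatives). On reconstructed published tables this
  construction yields p ≈ 0.22/0.34 where the source reported
  p = 0.005/0.009 — the published construction evidently differs (a
  paired McNemar-style test on the discordant samples is one candidate),
  and no stated construction reproduces those values from the available
  counts. The package reports its own construction and this caveat rather
  than an irreproducible number.
- Survival: Kaplan–Meier product-limit curves, two-group log-rank, and
  Cox proportional hazards with Efron tie handling (via lifelines), with
  constant covariates rejected by name. Medians are undefined (inf/NaN)
  while a curve stays above 0.5.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not biological realism:

- **Features**: multivariate normal, unit variance, organized into 8
  equicorrelated "cell-type" blocks (within-block r = 0.4 by default,
  block size ⌊p/9⌋) plus an independent remainder — mimicking the grouped
  correlation of immune cell-type signatures. No public description of
  the real panel's marginals exists; normality is a stand-in.
- **Outcome**: Bernoulli(sigmoid(b0 + x·β)) with β nonzero on 3 features
  (defaults 0.5/0.6/0.7) and b0 solved by bisection on the realized
  design so expected disease-control prevalence is 0.41. Effect sizes
  were calibrated once so that a fixed model on the informative features
  attains OOB AUC ≈ 0.76, the published operating point; the full
  pipeline's selected models score somewhat higher on their own training
  draw (selection optimism).
- **Survival**: proportional-hazards Weibull (shape 1 = exponential),
  log-hazard = baseline − 0.35 × centered latent predictor, baseline
  scale 12 months (median OS under null near the published 8–14 month
  range), independent exponential censoring calibrated to a 25% marginal
  censor rate plus a 48-month administrative cap.
- **Replicates**: base row + i.i.d. Gaussian noise, default SD 0.1 — an
  assay whose technical noise sits an order of magnitude below biological
  variation, as required of an assay that passes a 4·std ≤ 20 bound on
  the score scale.
- **Expression layer**: per-feature member genes with negative-binomial
  counts whose log2-mean equals the feature value plus a baseline, so
  signature scoring on log2 CPM recovers the features (round-trip
  Pearson/Spearman > 0.8 at low dispersion). This exercises the feature
  module end to end; it does not model UMI chemistry, 3' bias, batch or
  site effects.
- **Comparator**: a CPS-like integer 0–100 marker from the rank of a
  weighted feature combination plus noise — correlated with immune
  activity but noisier than the model score, like PD-L1 CPS.

What passing synthetic tests shows: the machinery (selection, scoring,
thresholding, evaluation) is correct and calibrated under the assumed
structure. What it does not show: performance on real FFPE RNA-seq, where
feature distributions are skewed, correlation is not block-constant, and
QC failures correlate with outcome.

## Problem sizes and numerics

Test and demonstration runs use study-scale cohorts (n = 103, 62
features) with B = 50–1000 bootstrap iterations, forward selection capped
at 4–5 features, and recovery suites of 5–20 seeded replicates — sizes
chosen so each property is measured with adequate statistical resolution.
Logistic fits use lbfgs at tol = 10⁻¹⁰; fits agree with brute-force
penalized-likelihood grid maximizers to < 10⁻³. Bisection for the
intercept runs 200 iterations on [−50, 50]. Equality tests on rounded
metrics compare exact binary doubles produced by the same half-up rule.

## Limitations

- The real 62-feature panel's identities and the exact signature
  transform are proprietary to the original assay; the panel here is
  configurable and the scoring (mean of member z-scores of log2 CPM) is a
  standard, stated substitute.
- The pooled OOB AUC null bias described above means chance-level
  performance reads as ≈ 0.43, not 0.50.
- Upstream read processing (trimming, alignment, counting) is out of
  scope; QC consumes precomputed metrics.
- No elastic-net/L1 variants, no .632(+) bias-corrected estimators, no
  refitting of the *selection* inside each bootstrap resample by default
  (the feature set is fixed; coefficients are refit per resample).
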
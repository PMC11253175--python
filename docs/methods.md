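# Methods

## The scoring model

The package centres on a logistic prognostic model of the 2-year
composite endpoint (cardiovascular death, urgent transplant, LVAD) in
HFrEF. For a patient with covariate vector
x = (peakVO2 % predicted, VE/VCO2 slope, Hb [g/dl], Na [mmol/L],
LVEF [%], MDRD eGFR [ml/min/1.73 m²]) the linear predictor is
esp = β₀ + βᵀx and the event probability e^esp/(1+e^esp). The
sex-recalibrated score keeps this functional form but uses a separate
coefficient set per sex; both published sets are stored at full printed
precision (seven significant decimals) and are the canonical definition
of the score — the coarser three-decimal roundings that circulate in
summary tables are not used. Covariates enter raw, in their clinical
units, with no internal rescaling; values outside plausibility bands
(e.g. Na outside 100–160 mmol/L) log a warning but are scored anyway,
since the score itself defines no exclusions.

The logistic transform is evaluated with `scipy.special.expit` and the
result clamped to the nearest representable double inside (0,1): beyond
|esp| ≈ 37 the logistic saturates past double precision, and a score
that returns an exact 0 or 1 breaks downstream log-odds round-trips.

Standardized coefficients are defined as β × SD(covariate), putting
weights for covariates with different units on a common
per-standard-deviation scale. This is one of several conventions in
use; when comparing against externally published standardized values,
note that alternatives (e.g. dividing by the latent-logistic residual
scale) differ by a sex-constant factor.

## Synthetic cohorts

`synthetic_cohort` generates tabular cohorts that mimic the HFrEF
registry population the score was recalibrated on: 1,444 women and
6,456 men by default, each sex's six covariates drawn from truncated
normals with the published per-sex means and SDs (women: peakVO2%
63.2 ± 18.3, VE/VCO2 33.5 ± 7.7, Hb 12.7 ± 1.4, Na 139.6 ± 3.0, LVEF
36.4 ± 11.4, MDRD 68.6 ± 24.6; men: 54.6 ± 17.0, 33.2 ± 7.9,
13.7 ± 1.7, 139.4 ± 3.3, 32.3 ± 10.0, 72.3 ± 24.2). Truncation bounds
default to mean ± 4 SD intersected with physiologic ranges (all
covariates positive, Na in [110, 160], LVEF in (0, 100]); this removes
impossible values while shifting the moments negligibly (the largest
shift, MDRD's floor at 0, moves the mean by ~0.2 against an SD of
~24). Sampling is by rejection from the untruncated (multivariate)
normal — exact within the bounds, and with acceptance ≈ 1 at ± 4 SD.

Events are Bernoulli draws from the logistic model under a "true"
coefficient set per sex, by default the published S-MECKI sets, so the
generator reproduces the registry's event-rate asymmetry (≈ 4.1% in
women vs ≈ 5.7% in men at the defaults). Everything is deterministic
given the spec seed, with per-sex child streams so changing one sex's
n does not perturb the other's draws.

The default correlation between covariates is identity, because the
published population summaries report no covariance structure; a full
per-sex correlation matrix can be supplied (real HF covariates do
correlate — Hb with eGFR, peakVO2 with VE/VCO2 — and identity is a
simplification). No censoring, missingness, treatment effects, or
enrollment-era structure is simulated; the endpoint is the 2-year
binary composite. Consequently, passing tests demonstrate the
statistical machinery recovers a known truth under clean conditions —
they do not validate the score's clinical accuracy, which only registry
data can.

## Weight estimation by repeated half-split cross-validation

For one sex's cohort: 200 times, the cohort is randomly divided in half
(training gets the extra record when n is odd; no outcome
stratification by default, since plain random division is the specified
procedure — a stratified option exists). On each training half a
7-parameter logistic model (intercept + six covariates, canonical
order) is fit by Newton/IRLS maximum likelihood, converged when every
score-equation component is < 1e-8 or the parameter step < 1e-10,
with at most 100 iterations and step-halving for stability. The fitted
linear predictor is scored on the held-out half by AUC. The mean of the
200 coefficient vectors is the recalibrated weight vector.

With ~30 events per female training half and seven parameters,
quasi-complete separation occasionally occurs; it is detected as
saturated fitted probabilities (< 1e-8 or > 1−1e-8) at an apparent
optimum or as outright non-convergence. A flagged repetition is refit
with a small L2 penalty (1e-4 on the non-intercept terms) and its
coefficients kept in the mean — dropping exactly the separated splits
would bias the weights — while its count is reported and its held-out
AUC excluded. If more than 25% of repetitions fail the procedure
aborts as degenerate. Repetition i draws its RNG stream from
(master_seed, i), so repetitions are order-independent and individually
reproducible.

95% intervals across repetitions are empirical 2.5/97.5 percentiles by
default; a normal-theory interval of the mean is also computed and
selectable. The percentile interval describes the spread of half-sample
fits (wide); the interval of the mean describes the precision of the
averaged weight (narrow). Published interval widths for this procedure
are much closer to the latter. The sex-difference symbol per variable
compares the two sexes' 95% intervals: overlapping (touching counts as
overlapping) ⇒ '=', otherwise '>' or '<' by which sex's weight is
larger in absolute value.

### What recovery can and cannot show at registry size

A single cohort of 1,444 women yields only ~60 events. The CV mean is
then dominated by the cohort's own sampling noise: across replicate
synthetic cohorts the recovered female intercept has SD ≈ 6.5 and the
female Hb weight SD ≈ 0.10 — larger than the weights themselves. The
recovery experiments therefore replicate the whole
simulate-and-recalibrate pipeline over fresh cohorts and average:
measured this way the procedure is unbiased for every coefficient (a
200-replicate pilot bounds the female intercept bias at ≈ 0.1 ± 0.46,
and all slope biases at well under 5% of the true value). The
acceptance checks use 400 female / 100 male replicate cohorts
(~5 minutes on one CPU), sized so that the Monte-Carlo SE of each
averaged coefficient is small against its tolerance.

## Evaluation

**AUC** is the Mann–Whitney concordance (ties count 1/2), computed by
midranks; it matches brute-force pair counting exactly.

**DeLong test**: placement values (structural components) per positive
and per negative give each score's AUC; the covariance of the paired
AUCs is the empirical covariance of the placement values; the test is
z = ΔAUC/√var with a two-sided normal p (the conventional reading, as
sidedness is rarely stated in applied reports). Zero variance with
equal AUCs returns p = 1 by convention; zero variance with unequal
AUCs is an error.

**Hosmer–Lemeshow**: patients are split into deciles of predicted
risk — stable sort on (predicted, index) then near-equal splits, so
grouping is deterministic under ties; if there are fewer distinct
predicted values than groups the call fails with advice to reduce the
group count. The statistic is Σ (O−E)²/(E(1−p̄)) with p̄ the group mean
risk. Degrees of freedom are g−2 by default (the classical choice when
the model was fit on the same data); `external=True` uses g−1 for
externally specified probabilities. Note the statistic's null mean with
fully external probabilities is close to g itself, so the g−2 reference
is conservative in the validation direction; the null-behaviour test
uses the external convention. A group whose expected events hit 0 or
its full size gets a 0.5-event continuity floor (with a warning) so
small synthetic cohorts do not crash.

## Pipeline

`run_study` is a pure function of (input, config): descriptives with
Welch t and chi-square (no continuity correction, p values unadjusted),
per-sex CV with the symbol column, standardized betas from the observed
per-sex covariate SDs, native-vs-recalibrated DeLong comparisons
overall and within sex, and decile calibration of both scores. When no
pooled "native" coefficient set is supplied, the comparator is a pooled
logistic fit on the input cohort itself, making the pipeline
self-contained. Outputs are stamped with a config hash and the master
seed, and reruns are byte-identical.

## Problem sizes used in the checks

Unit and property tests run on cohorts of tens to a few thousand rows.
The recovery checks use the registry sample sizes (1,444 / 6,456) with
the full 200-repetition CV, averaged over 400 / 100 replicate cohorts
in the test suite and 300 / 150 in the acceptance script. The
calibration null experiment uses 50,000 patients × 100 outcome draws;
the DeLong-vs-bootstrap comparison uses ten 30-patient instances ×
20,000 resamples.

## Known limitations

- Identity covariate correlation by default; real covariate dependence
  would change the weights' joint sampling behaviour (not their
  unbiasedness).
- The binary 2-year endpoint ignores censoring; a cohort with
  substantial early dropout would need a time-to-event treatment that
  is out of scope here.
- The standardized-beta convention (β × SD) is one of several; compare
  conventions before comparing numbers across publications.
- The native MECKI comparator defaults to an in-sample pooled fit, not
  the originally published pooled coefficients (which can be supplied
  via config when available).
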
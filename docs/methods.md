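# Methods

`svyscan` implements a design-based association analysis of urinary
biomarker exposures with a self-reported binary outcome in a complex
survey sample, together with the validation and sensitivity machinery
such an analysis needs when the outcome is self-reported. This note
records the statistical procedures, the modelling assumptions, the
defaults and why they were chosen, and what the synthetic cohort
generator does and does not emulate.

## Exposure processing

**LOD substitution.** Assay readings below the limit of detection are
replaced by LOD/2 — the conventional single-value substitution. No
maximum-likelihood or multiple-imputation treatment of the censoring is
attempted; with the rank-based normalisation that follows, all censored
values of a metabolite land in a single tied block at the bottom of the
ranking, so the choice of substitution constant below the LOD is
irrelevant to everything downstream.

**Dilution correction.** Spot-urine concentrations are corrected for
dilution by the log ratio ln(analyte / urinary creatinine). The units
of the ratio are deliberately mixed (ng/mL over mg/dL) and the base of
the logarithm is immaterial: both contribute only additive/multiplicative
constants, which the rank-based step removes. Natural log is used.

**Inverse normal transformation.** The dilution-corrected values are
ranked (average rank on ties), mapped to empirical CDF points, and
passed through the standard-normal quantile function, yielding scores
that are N(0,1) up to rank granularity. The CDF convention is
`rank/(n+1)` by default — it keeps all quantiles finite — with Blom
`(rank-3/8)/(n+1/4)` and Hazen `(rank-1/2)/n` available via the
`offset` argument, since survey-software recipes differ on this point
and the choice is not identifiable from a verbal description. Ranks are
pooled across the whole analysis sample (not within survey cycle).
Odds ratios for transformed exposures are therefore per standard
deviation of the dilution-corrected distribution. If every value is
tied the transform is undefined; the package warns and returns zeros.

## Design-based estimation

Estimation follows the Taylor-linearization ("with replacement"
first-stage) approach of the major survey packages:

* Means and proportions are Horvitz–Thompson ratio estimates
  Σwᵢyᵢ/Σwᵢ. Their variance sums, over strata h with n_h sampled PSUs,
  n_h/(n_h−1) times the squared deviations of PSU totals of the
  linearized residuals wᵢ(yᵢ−θ̂)/Σwᵢ from their stratum mean.
* Logistic regression maximises the weighted pseudo-log-likelihood by
  IRLS (tolerance 1e−10 on the max coefficient change, at most 100
  iterations; coefficients exceeding 50 in absolute value are treated
  as complete separation and raised as an error). The covariance is
  the sandwich B·V·B with bread B = (XᵀWX)⁻¹ from the weighted
  information and meat V the stratified between-PSU covariance of
  PSU-aggregated weighted scores wᵢ(yᵢ−pᵢ)xᵢ.
* Design degrees of freedom are `#PSUs − #strata`; confidence
  intervals use a t multiplier with that df and p-values are two-sided
  t tests — the convention of the survey software family this mirrors,
  chosen so results are comparable with published survey analyses.
* Strata containing a single PSU are a hard error by default; an
  explicit `singleton="center"` mode instead centers that PSU's score
  total at the grand mean across PSUs, which public-release subsets
  sometimes require. No finite-population correction and no
  replicate-weight (BRR/jackknife) variance are provided.
* Pooling several release cycles divides the weights by the cycle
  count. All ratio estimates, SEs and p-values are invariant to weight
  scale, so this matters only for estimated population totals; the
  default cycle count is 1.

Missing covariate values are **not** dropped: the covariate coding maps
every "unknown/refused/not measured" to code 0 before modelling, so the
estimator itself requires complete numeric input and every subject
enters every model. This preserves the sample across the nested model
sequence at the cost of treating missingness as its own (reference-ish)
category — a deliberate trade, recorded here because it differs from
the listwise deletion many regression defaults apply.

## The association scan

The univariate scan fits one design-based logistic model per metabolite
(outcome ~ one transformed exposure) and applies a Bonferroni
correction with the family size fixed a priori at the panel size
(m = 12), capped at 1, regardless of how many fits succeed. The nested
analysis is a **fixed cumulative sequence**, not data-driven selection:
model 1 contains all 12 metabolites; models 2–16 add age, sex,
Hispanic ethnicity, marital status, education, poverty-income ratio,
physical activity, HbA1c stratum, total cholesterol stratum, HDL
stratum, triglyceride stratum, hypertension, diabetes duration, calorie
quartile and obesity, in that order, each retaining everything before
it. The exposure of interest's coefficient is reported per model.
Collinear models are flagged and skipped; the sequence continues.

The DnOP specificity analysis sums the two di-n-octyl phthalate
metabolites on the molar scale: MOP/278.34 + MCPP/252.22 (g/mol from
the molecular formulas C₁₆H₂₂O₄ and C₁₂H₁₂O₆; ng/mL over g/mol is
µmol/L), then treats the sum as an ordinary exposure.

## Outcome validation

The 4-level imaging grade collapses to a binary standard with
"positive" = moderate/severe non-proliferative or proliferative
retinopathy; mild NPR counts as negative, because mild disease is
unlikely to have produced the physician communication the self-report
question asks about. Agreement is summarised by raw percent agreement
and Cohen's kappa with its large-sample SE and a test of κ = 0
(delegated to statsmodels); a design-weighted kappa variant replaces
counts by weight sums and is reported as a point estimate only, since
the simple-random-sample SE theory does not apply to it. Both raw and
design-weighted misclassification rates are extracted: the share of
self-report-positives without imaging confirmation and the share of
self-report-negatives with confirmed moderate-or-worse disease. Under
strongly unequal weights the raw and weighted shares can differ by
several-fold; both are always reported.

## Misclassification Monte Carlo

The sensitivity analysis takes the two misclassification rates as fixed
inputs (defaults 0.112 and 0.0492, the design-corrected rates a
validation substudy of this kind yields) rather than recomputing them,
and per replicate flips each **observed** case to control with
probability fp and each observed control to case with probability fn —
independent Bernoulli flips, not count-preserving swaps (a
`balanced_flips` flag provides the latter). The full covariate model is
refit per replicate; IRLS warm-starts from the base fit, which cannot
change the optimum at tolerance 1e−10 and is asserted against cold
starts in the tests. Replicates that fail to converge are dropped;
more than 5% failures aborts. The summary is the mean and SD of the
replicate coefficients with the normal-theory interval
exp(mean ± z·SD) — the parametrisation consistent with reporting a
mean coefficient alongside an interval whose endpoints back-solve to
that mean and SD — plus a percentile interval for comparison. With both
rates zero no reshuffling occurs and the summary collapses exactly to
the base fit with SD 0. Nondifferential flipping of this kind biases
the coefficient toward the null, so the replicate mean sits between 0
and the error-free estimate; the tests verify this attenuation.

## Dose-response

Because transformed exposures are standard-normal scores, subjects are
binned at −1, 0, +1 (lowest bin closed on the right: z = −1 is "more
than 1 SD below"); expected occupancies are 15.9/34.1/34.1/15.9%.
Prevalence per bin is design-corrected, but the Cochran–Armitage trend
chi-square runs on the **unweighted** counts with integer scores 1–4 —
the classical test, with a design-based logistic fit on the category
index emitted alongside as the weighted sensitivity check. The
statistic is invariant to affine score changes; zero-total bins are
dropped with a warning. Bins use the scores as produced (already
N(0,1)); no re-standardisation by weighted moments is applied.

## The synthetic cohort generator

The generator exists so the whole pipeline can be exercised against
known truth. It emulates: a stratified design with 15 strata × 2 PSUs
(design df 15, the order of magnitude of a pooled national survey
subsample) and log-normal weights (log-SD 0.7); twelve correlated
log-normal metabolite concentrations (unit log-SD; a 0.2 background
correlation with tighter DEHP-metabolite (0.6–0.8), DnOP (0.4) and
butyl-isomer (0.5) blocks, projected to the nearest PSD correlation
matrix) censored at per-metabolite LODs, with MOP's at 0.84 ng/mL;
log-normal creatinine around 100 mg/dL; covariates drawn to match the
published category frequencies including their missingness; a true
outcome from a logistic model on the transformed exposures with default
effect OR 1.39 per SD of MOP, all others null, and intercept −1.82
(≈14% prevalence); an imaging substudy covering 28.4% of subjects; and
screening answers such that ~93% of generated subjects pass the
inclusion criteria.

Self-report is derived from the true outcome with **truth-conditional**
error rates — P(report | no disease) = fp, P(no report | disease) = fn,
the sensitivity/specificity parametrisation natural for generation —
while the validation extractor and the Monte Carlo operate on
**reported-conditional** shares. The two differ whenever prevalence is
not 50%; the generator round-trip test derives the reported-conditional
values implied by the generating rates and checks recovery against
those. Imaging grades are assigned from the true outcome by
configurable multinomials (cases: mild 0.25 / moderate-severe 0.60 /
PR 0.15; controls: none 0.90 / mild 0.10), so the imaging standard is
only a perfect proxy for truth when the case-mild probability is set to
zero, as the round-trip test does. Undiagnosed (HbA1c-qualified)
subjects carry no age at diagnosis and fall into the "unknown" duration
stratum, code 0.

What the generator does **not** emulate: real multistage selection
probabilities (weights are i.i.d. draws, uncorrelated with outcomes or
exposures — so weighted and unweighted estimates differ less than in
real data), within-PSU intra-class correlation beyond what the shared
design labels induce (none, so design SEs are close to SRS SEs and the
design machinery is validated by oracle tests rather than by realistic
clustering), covariate–exposure confounding (covariate effects default
to null), temporal or cycle structure, and any biology linking the
grade multinomial to exposure dose. Passing end-to-end tests therefore
demonstrates correctness of the estimators and plumbing under a known
truth, not robustness to design features the generator leaves out.

All randomness descends from a single seed through named substreams
(design, exposures, creatinine, covariates, outcome, self-report,
substudy, eligibility), so regenerating with the same configuration is
bit-reproducible and individual components can be varied in isolation.

## Numerical choices and degenerate inputs

IRLS linear predictors are clipped at ±30 before the logistic link to
avoid overflow; convergence is declared on a 1e−10 max coefficient
change; separation raises rather than returning a huge finite estimate.
All-tied exposure columns transform to zeros with a warning and then
fail the regression (constant predictor) in a flagged, non-fatal way
inside the scans. Kappa on a table with an empty margin raises.
Problem sizes in the test-suite simulations (cohorts of 600–2,000,
200 replications for calibration/recovery, 500 Monte Carlo replicates)
were chosen as the smallest sizes at which the Monte Carlo error bands
quoted in the tests are meaningful; the package defaults remain at the
full study scale (5,000 replicates).

## Known limitations

* LOD handling is substitution-only; heavy censoring (most of a column
  below LOD) collapses that exposure toward a binary detect/non-detect
  split after ranking.
* The design-weighted kappa has no attached SE.
* The trend test mixes weighted prevalences with an unweighted
  chi-square, as classical practice does; the weighted logistic trend
  is reported alongside for users who want a fully design-based answer.
* Misclassification rates enter the Monte Carlo as fixed constants; no
  prior distribution over the rates (full probabilistic bias analysis)
  is implemented.
* The nested-model covariate list is the 15-block sequence described
  above; extending it to a richer covariate set is configuration, not
  code, but no richer default ships.
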
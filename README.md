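# svyscan

Design-based association scanning of urinary biomarker exposures with a
self-reported binary outcome, for epidemiologists analysing complex
survey data (stratified, clustered, unequally weighted — the design of
national health examination surveys). The package grew out of the
analysis of urinary phthalate metabolites and diabetic eye complications
and implements that analysis end to end, but every stage is generic:

1. **Exposure transform** — LOD/2 substitution for readings below the
   assay detection limit, urine-dilution correction by the log ratio to
   creatinine, and a rank-based inverse normal transformation so every
   exposure enters regression as an N(0,1) score (odds ratios per SD).
2. **Survey estimation** — Horvitz–Thompson proportions/means and
   pseudo-maximum-likelihood logistic regression with Taylor-linearized
   (stratum/PSU sandwich) variance, t(df = #PSUs − #strata) inference:

   β̂ maximises Σᵢ wᵢ[yᵢ log pᵢ + (1−yᵢ)log(1−pᵢ)],
   V̂(β̂) = B [Σₕ nₕ/(nₕ−1) Σⱼ (z_hj−z̄_h)(z_hj−z̄_h)ᵀ] B,
   with B = (XᵀWX)⁻¹ and z_hj the PSU totals of wᵢ(yᵢ−pᵢ)xᵢ.
3. **Association scan** — one model per metabolite with a Bonferroni
   correction (m = 12), a fixed cumulative sequence of 16 multivariable
   models (11 co-exposures, then 15 covariate blocks coded with
   missing → 0 so no subject is ever dropped), and a molar-sum
   specificity analysis for metabolites sharing a parent compound.
4. **Outcome validation** — cross-tabulation of the self-report against
   a 4-level imaging grade, percent agreement, Cohen's κ with SE and
   test, and extraction of the two misclassification rates (raw and
   design-weighted).
5. **Misclassification Monte Carlo** — quantitative bias analysis:
   reshuffle observed cases/controls at the validation-derived rates,
   refit the full model per replicate, summarise the coefficient
   distribution as exp(mean ± z·SD).
6. **Dose-response** — SD-category binning of the transformed exposure
   (cuts at −1, 0, +1), design-corrected prevalence per bin, and the
   Cochran–Armitage chi-square test for linear trend.
7. **Synthetic cohort generator** — NHANES-like cohorts with known
   ground truth (true log-ORs, true reporting-error rates, LOD
   censoring, survey design), so the whole pipeline is testable without
   restricted data.

Core estimators follow scikit-learn conventions
(`SurveyLogisticRegression().fit(X, y, design=...)`,
`InverseNormalTransformer().fit_transform(X)`); the pipeline stages are
plain functions over them, and a `svyscan` command-line tool runs the
stages on CSV/TSV (or SAS XPORT) files.

## Worked example

```python
import pandas as pd
import svyscan as sv

cfg = sv.GeneratorConfig(n_subjects=2000, seed=1)      # true MOP OR 1.39/SD
cohort = sv.apply_inclusion_criteria(sv.generate_cohort(cfg))
z = sv.transform_exposures(cohort, sv.METABOLITES, cfg.resolve().lods)
coded = sv.encode_covariates(cohort)
df = pd.concat([cohort.drop(columns=coded.columns.intersection(cohort.columns)),
                z, coded], axis=1)
design = sv.SurveyDesign.from_frame(df)

scan = sv.univariate_scan(df, design)
print(scan.loc[["z_MOP"], ["odds_ratio", "or_low", "or_high", "p", "p_bonferroni"]])
nested = sv.nested_models(df, design)
print(nested.loc[[1, 16], ["odds_ratio", "or_low", "or_high", "p"]])
mc = sv.run_misclass_mc(df, design, sv.MCConfig(n_replicates=500, seed=1))
print(f"MC OR {mc.odds_ratio:.2f} (95% CI {mc.ci_low:.2f}-{mc.ci_high:.2f})")
tr = sv.trend_analysis(df, design)
print(tr.table[["n", "cases", "prevalence_weighted"]].round(3))
print(f"Cochran-Armitage chi2 {tr.statistic:.2f}, p {tr.p_value:.4f}")
```

prints

```
          odds_ratio  or_low  or_high      p  p_bonferroni
exposure
z_MOP          1.164   1.013    1.338  0.034         0.408

       odds_ratio  or_low  or_high      p
model
1           1.308   1.089    1.570  0.007
16          1.309   1.088    1.574  0.007

MC OR 1.23 (95% CI 1.10-1.38)

             n  cases  prevalence_weighted
category
<=-1 SD    289     45                0.146
(-1,0] SD  624    121                0.208
(0,1] SD   624    136                0.212
>+1 SD     289     71                0.231
Cochran-Armitage chi2 8.25, p 0.0041
```

Reading this: the univariate odds ratio for the transformed MOP score
(1.16 per SD) is attenuated below the generating truth of 1.39 because
the self-reported outcome carries the configured 11.2%/4.92% reporting
errors; adjusting for the correlated co-exposures (model 1) moves it to
1.31, and the fully adjusted model 16 leaves it essentially unchanged
since the generated covariates are null. The Monte Carlo — which flips
already-misreported outcomes again — attenuates further (OR 1.23) while
remaining clearly above 1, and the weighted prevalence rises
monotonically across the four SD bins with a significant linear trend.

The same run from a shell:

```sh
svyscan simulate --n 2000 --seed 1 --out cohort.csv
svyscan run-all --input cohort.csv --seed 1 --out results/
```

writes `selection_flow.csv`, `transformed.csv`, `univariate_scan.csv`,
`nested_models.csv`, `validation_table.csv`, `validation_summary.csv`,
`misclass_mc_*.csv`, `trend.csv` and a closing `report.md`.

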
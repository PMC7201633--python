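# akinet

Acute kidney injury (AKI) risk modelling for hospitalized patients with
hematologic malignancies (HM: lymphoma, leukemia, multiple myeloma), built as
a reusable, tested pipeline:

1. **Synthetic cohort generation** — admission records (demographics,
   comorbidities, admission labs, serum-creatinine time series) with the
   marginal structure of a published 2395-patient HM cohort and a *known*
   ground-truth dependency graph, so every downstream method can be validated
   by recovery experiments.
2. **Clinical coding** — eligibility filters (length of stay ≥ 24 h, no
   baseline dialysis/RRT, ≥ 2 creatinine tests), KDIGO creatinine-based AKI
   detection and staging, and discretization of labs into the published
   clinical bands.
3. **Univariate epidemiology** — per-variable counts, Pearson χ² (no
   continuity correction), Cochran–Mantel–Haenszel trend tests for ordinal
   exposures, and crude odds ratios with Woolf 95% CIs.
4. **Group-LASSO variable selection** — penalized logistic regression over
   grouped dummies, `argmin (1/n)·NLL(β₀,β) + λ Σⱼ √pⱼ‖βⱼ‖₂`, solved by block
   coordinate descent with within-group orthonormalization; λ path, AIC/BIC/GCV
   selection, and stratified 10-fold cross-validated `lambda.min`.
5. **Discrete Bayesian network** — DAG + CPTs with the factorization
   `P(X₁..Xₙ) = Πᵢ P(Xᵢ | π(Xᵢ))`; BIC-scored tabu-search structure learning,
   maximum-likelihood CPTs, and inference by exact enumeration, likelihood
   weighting, and logic (rejection) sampling.
6. **Evaluation** — BN posterior risk scores under arbitrary partial
   evidence, ROC/AUC with DeLong CIs, an unpenalized logistic baseline, and
   stratified k-fold cross-validation that re-runs the *entire* pipeline per
   fold.

The intended audience is clinical epidemiologists and methodologists who want
an end-to-end, inspectable reference implementation of the
"group-LASSO screening → Bayesian-network modelling" workflow for binary
clinical outcomes.

## Worked example

Exact statistics from the packaged risk-factor table (counts are shipped
verbatim as a fixture):

```python
from akinet.synthetic import table1_fixture
from akinet.epi import crude_or, pearson_chi2, overall_incidence

fx = table1_fixture()
print(f"overall AKI incidence: {overall_incidence(fx):.1f}%")
res = crude_or(fx["gender"], "female")
chi2, df, p = pearson_chi2(fx["gender"])
print(f"female vs male: cOR {res.odds_ratio:.2f} "
      f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}), chi2 {chi2:.3f}, p = {p:.3f}")
```

prints

```
overall AKI incidence: 15.4%
female vs male: cOR 1.44 (95% CI 1.16-1.80), chi2 10.561, p = 0.001
```

i.e. 15.4% of admissions develop AKI, and female patients have 1.44-fold
higher odds of AKI than male patients.

Full pipeline on a synthetic cohort:

```python
from akinet.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, n_patients=1200, glasso_n_lambda=50, eval_k=5)
s = run_pipeline(cfg, "out")
print(", ".join(s["groups_selected"]))
print(f"BN AUC {s['bn_auc']:.3f} | logistic AUC {s['logistic_auc']:.3f} "
      f"| CV AUC {s['cv_auc']:.3f}")
print(f"P(AKI | abnormal labs) = {100*s['scenario_abnormal_p_aki']:.1f}%  ->  "
      f"corrected: {100*s['scenario_corrected_p_aki']:.1f}%")
```

prints

```
age_band, gender, hypertension, hm_category, scr_high, egfr_band, hb_low, sodium_band, potassium_band
BN AUC 0.832 | logistic AUC 0.853 | CV AUC 0.809
P(AKI | abnormal labs) = 81.0%  ->  corrected: 3.3%
```

The BIC-selected predictor groups feed tabu-search structure learning; the
fitted network discriminates AKI from non-AKI admissions (AUC ≈ 0.83 in
sample, ≈ 0.81 under 5-fold cross-validation of the whole pipeline), and
evidence propagation quantifies how much the AKI posterior drops when
admission anemia, renal impairment, hyperuricemia and hyponatremia are
corrected to normal levels.

The same stages are available from a shell via the `akinet` console script
(`simulate`, `code`, `stats`, `glasso`, `bn-learn`, `bn-infer`, `evaluate`,
`run-all`); networks are exported as canonical JSON and as BIF for use with
standard BN tools.

## Documentation

`docs/methods.md` describes the statistical model, the generator's design and
its calibration, numerical choices, and known limitations.
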
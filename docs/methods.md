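# Methods

## Problem setting

Hospitalized patients with hematologic malignancies (HM) develop acute
kidney injury (AKI) at high rates, and their risk factors — renal function,
anemia, electrolyte disturbance, malignancy category, anti-tumor treatment —
are strongly interdependent, which undermines the independence assumptions
of ordinary logistic score models. The pipeline implemented here treats AKI
risk modelling in two stages: a group-LASSO screen reduces the categorical
predictor set, and a discrete Bayesian network (BN) over the retained
variables models their joint dependence structure and supports posterior
risk queries under *partial* evidence (any subset of a patient's variables
may be unobserved at query time).

## KDIGO AKI coding

AKI is detected from the serum-creatinine (SCr) series alone (urine-output
criteria are intentionally out of scope; admission records rarely date urine
volumes reliably). Two clauses are checked for every measurement:

* **delta48h**: an absolute rise ≥ 0.3 mg/dL (26.5 µmol/L, the unit used
  throughout) relative to any measurement in the preceding 48 h;
* **fold7d**: a value ≥ 1.5× the *running baseline*, defined as the minimum
  SCr in the preceding 168 h. The rolling-minimum baseline is an
  operational choice (common in EMR-based AKI detection); the equivalent
  pairwise formulation — some pair (i, j) within 168 h with
  `scr_j / scr_i ≥ 1.5` — is used as an independent test oracle.

Staging takes the maximum over the admission: stage 1 for fold change in
[1.5, 2.0) or a delta48h hit alone; stage 2 for [2.0, 3.0); stage 3 for
≥ 3.0-fold or an absolute SCr ≥ 4.0 mg/dL (353.6 µmol/L) once AKI has
triggered. (A printed stage-2 band of "≥2.9–3.0-fold" in the source
guideline transcription is treated as a typo for the standard KDIGO
2.0–2.9 band.) When both clauses first fire at the same measurement, the
trigger is reported as `fold7d`. Band edges for the discretized labs follow
the published cutoffs exactly (e.g. sodium reference 137–147 mmol/L,
hyperkalemia > 5.3 mmol/L, anemia Hb < 115 g/L); age 29 closes the first
age band. Missing labs yield an explicit missing marker and are never
imputed.

## Synthetic cohort generator

No patient-level data are distributable, so the generator is a first-class
module that emulates the published cohort's *marginals* on top of a known
ground-truth graph:

* All 18 coded predictors plus the AKI outcome form a Bayesian network.
  Root nodes carry the published category frequencies (e.g. P(male) =
  1375/2395). Three child structures encode the qualitative dependency
  skeleton: HM category → anemia; HM category and diabetes → eGFR band
  (cumulative-logit); and {age band, anemia, eGFR band, sodium band,
  potassium band} → AKI (logistic).
* Child-node intercepts/thresholds are solved by 1-D root finding
  (`brentq`) so the *implied marginals equal the published frequencies
  exactly*; dependence strengths are free parameters (the source reports
  no pairwise associations) and default to strong, monotone log-odds
  effects — abnormal levels always increase AKI risk — chosen once so that
  graph- and group-recovery experiments have a well-defined signal.
* SCr trajectories are constructed to be label-consistent: AKI-destined
  patients receive a rise of ≥ 1.55× baseline inside a 48 h window, with
  the multiplier range encoding the intended stage (stage mix 308/41/21 of
  370, as published); non-AKI patients receive jitter bounded by
  min(9% of baseline, 12 µmol/L), which cannot reach either KDIGO clause.
  Re-coding simulated records reproduces the intended AKI *label* for 100%
  of patients in practice (the guarantee tested is ≥ 99%). The intended
  *stage* can be upgraded to 3 by the absolute 353.6 µmol/L clause in
  high-baseline (SCr ≥ 115) patients — about 0.3% of records — which is
  correct detector behaviour, not a generator defect.
* Continuous labs are drawn uniformly inside the sampled band, so coding is
  exactly invertible; an optional missing-at-random mask (default rate 0)
  exercises the pipeline's missing-data contract.

What the generator does **not** emulate: the real cohort's joint
distribution beyond these marginals and the stated skeleton (e.g. the
correlation between SCr and eGFR is not enforced), hospital-process detail
(RRT timing, readmissions), or measurement error in labs. Passing recovery
tests therefore demonstrates the *methods* behave correctly under known
conditions, not that the fitted synthetic networks estimate any real-world
quantity.

## Univariate statistics

Pearson χ² is computed without continuity correction (this reproduces the
published statistics to the printed precision on every 2×2 and R×2 table).
The CMH trend test for ordinal exposures (age, eGFR, uric-acid bands) is the
Mantel–Haenszel correlation form `(N−1)·r²` with integer scores 1..K; this
reproduces the published uric-acid value exactly, while the published age
and eGFR values do not match any scoring convention we tried and are treated
as soft diagnostics only. Crude odds ratios use the reference rows that the
printed table layout leaves implicit (derived by subtraction); CIs are
Woolf (log-normal). Zero cells raise unless a Haldane–Anscombe 0.5
correction is explicitly enabled.

## Group LASSO

The estimator minimizes the mean binomial deviance plus
`λ Σⱼ √pⱼ ‖βⱼ‖₂` over reference-omitted dummy groups. Binomial deviance is
used rather than a squared-error loss because the outcome is binary and the
reference tooling for this workflow (grpreg) fits the logistic family; the
√pⱼ group multiplier likewise follows that convention. The solver is block
coordinate descent on a quadratic majorization of the logistic loss
(curvature bound 1/4), after centering and within-group orthonormalization
(SVD; rank-deficient groups keep their nonzero singular directions), so each
block update is the closed-form group soft-threshold; coefficients are
back-transformed for reporting. Convergence: sup-norm change < 1e-7, at
most 10⁴ cycles; λ grid: 100 log-spaced values from λ_max (closed form from
the null-model KKT condition) down to 0.001·λ_max, warm-started.

Model size df is counted as the number of nonzero coefficients plus the
intercept; AIC/BIC/GCV are computed from the penalized fit's deviance, and
ties in a criterion resolve to the smallest λ. A known property of this
single-path selection (verified experimentally here and insensitive to
effect size): the truth groups are recovered with essentially no misses at
n = 5000, but 1–3 weakly-correlated noise groups are additionally admitted
in roughly half of replicates, because un-shrinking the strong groups
requires moving λ below the noise groups' entry points. Cross-validated
`lambda.min` (stratified folds, shared λ grid, mean held-out deviance) is
deliberately prediction-oriented and over-selects further; on permuted
(signal-free) outcomes it returns an empty or near-empty model in the clear
majority — but not all — of replicates.

## Bayesian network

Structure learning maximizes the decomposable BIC score
`Σᵢ [LLᵢ − (dᵢ/2)·ln N]` with `dᵢ = (levelsᵢ−1)·Π(parent levels)` by tabu
search over arc additions, deletions and reversals (tabu list of inverse
moves, default length 10; aspiration for new global optima; deterministic
lexicographic tie-breaks; optional random restarts, whitelists and
blacklists; acyclicity checked before every move). BIC is chosen as the
score because it is the standard default for discrete tabu search and
matches the λ-selection criterion used upstream. Learning is complete-case;
missingness is handled natively only at inference time (partial evidence).
No constraint forces AKI to be a sink, so arcs incident to AKI may be
oriented either way within the score-equivalence class; evaluation
therefore treats AKI's *neighborhood*, not its parent set alone, as the
object of interest.

Parameters are maximum-likelihood CPT rows with optional pseudo-counts;
parent configurations never observed fall back to uniform rows with a
warning, which keeps inference free of structurally impossible evidence.
Inference engines: exact enumeration over the ancestral set of query and
evidence (guarded at 2²⁰ configurations), likelihood weighting (evidence
clamped, samples weighted by evidence likelihood, ratio-estimator standard
errors), and logic sampling (forward sampling with rejection). With no
evidence the two samplers are by construction identical draw-for-draw.
Scenario inference batches evidence sets over a shared seed and reports the
delta against the no-evidence marginal. The default scenario pair contrasts
admission anemia + renal impairment + hyperuricemia + hyponatremia with the
same labs corrected to normal; very rare extreme levels (e.g. hyperkalemia,
prevalence ~1%) are deliberately not used as scenario evidence because
their ML CPT cells are poorly supported at cohort scale.

## Evaluation

AUC is the normalized Mann–Whitney U (ties at half weight; verified exactly
against all-pairs concordance), with DeLong confidence intervals by default
and a seeded stratified bootstrap by flag. The logistic baseline is an
unpenalized GLM on the selected predictors (a 1e-6 ridge fallback handles
separation). Cross-validation is stratified (at 15% prevalence unstratified
folds are fragile) and re-runs the entire pipeline — selection, structure
learning, CPT fitting — inside each training fold; held-out scores are
pooled into a single ROC. The published "accuracy comparison" between
full-data and cross-validated models is not fully specified at the source;
it is implemented, and labelled, as a Mantel–Haenszel χ² on
correct/incorrect classification counts at the full ROC's Youden-optimal
threshold, stratified by true outcome. In-sample, the saturated-dummy
logistic baseline is typically within ~0.02 AUC of (and often slightly
above) the BN score on this generator's additive truth model; the BN's
practical advantage is prediction under partial evidence, which the
logistic score model cannot do at all.

## Determinism and problem sizes

A single pipeline seed fans out to per-stage seeds through
`SeedSequence((seed, stage))`, so stages are independently reproducible and
a rerun with the same configuration is byte-identical artifact-for-artifact.
Default study conditions follow the published cohort: 2395 patients, 18
candidate predictor groups, 10-fold cross-validation. Recovery experiments
use N = 5000 (structure and group recovery) and 100 random ≤ 5-node
networks at 50 000 samples (inference agreement); the test suite runs
scaled-down versions of the most expensive experiments (e.g. 8 permutation
replicates at n = 1500) and states each size in the test body.

## Known limitations

* The generator's dependence strengths are stipulated, not estimated; none
  of the fitted synthetic AUCs or posteriors estimate real-cohort values.
* Path-based BIC selection does not achieve exact support recovery (see
  above); users wanting exact-support experiments should combine the path
  with a refit/stability step, which is out of scope here.
* EM-based learning from incomplete data, concave group penalties
  (grMCP/grSCAD) and bi-level selection (gel/cMCP), constraint-based and
  hybrid structure learning, and causal interpretation of learned arcs are
  all out of scope; arcs encode probabilistic dependence only.
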
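"""End-to-end pipeline: simulate -> code -> stats -> gLASSO -> BN -> evaluate.

Every stage draws its randomness from a seed derived from the single
top-level seed by a splittable counter scheme, so each stage is
independently reproducible and the whole run is byte-deterministic.  JSON
artifacts carry a provenance header (config hash + stage seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bn as bnmod
from .coding import CODED_LEVELS, apply_eligibility, code_cohort, data_dictionary
from .epi import report_to_frame, report_to_json, table1_report
from .evaluate import auc, crossvalidate, logistic_baseline, predict_frame
from .glasso import build_design, cv_lambda, fit_path, select_ic
from .io import (config_hash, write_coded_csv, write_cohort_csv, write_json,
                 write_scr_series_csv)
from .synthetic import CohortParams, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "fit_predictive_model", "predict_model"]

PREDICTORS = tuple(v for v in CODED_LEVELS if v not in ("aki", "aki_stage"))

# evidence-propagation scenarios: anemia + renal impairment + hyperuricemia +
# hyponatremia on admission, versus the same labs corrected to normal (rare
# extreme levels such as hyperkalemia are avoided: their ML-fitted CPT cells
# are poorly supported at cohort scale)
_WORST = {"hb_low": "yes", "egfr_band": "<=59", "sodium_band": "hypo",
          "sua_band": ">=481"}
_CORRECTED = {"hb_low": "no", "egfr_band": ">=90", "sodium_band": "normal",
              "sua_band": "<=359"}


@dataclass
class PipelineConfig:
    """Schema-validated run configuration; unknown keys are rejected."""

    seed: int = 0
    n_patients: int = 2395
    missing_rate: float = 0.0
    apply_eligibility_filters: bool = True
    glasso_criterion: str = "BIC"       # AIC | BIC | GCV
    glasso_selection: str = "ic"        # "ic" or "cv" (lambda.min)
    glasso_k: int = 10
    glasso_n_lambda: int = 100
    glasso_lambda_min_ratio: float = 0.001
    bn_tabu_len: int = 10
    bn_max_iter: int = 10_000
    bn_restarts: int = 0
    bn_smoothing: float = 0.0
    bn_whitelist: tuple[tuple[str, str], ...] = ()
    bn_blacklist: tuple[tuple[str, str], ...] = ()
    eval_k: int = 10
    ci_method: str = "delong"
    scenario_samples: int = 100_000

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.glasso_criterion.upper() not in ("AIC", "BIC", "GCV"):
            raise ValueError("glasso_criterion must be AIC, BIC or GCV")
        if self.glasso_selection not in ("ic", "cv"):
            raise ValueError("glasso_selection must be 'ic' or 'cv'")
        if self.ci_method not in ("delong", "bootstrap"):
            raise ValueError("ci_method must be 'delong' or 'bootstrap'")
        if self.eval_k < 2 or self.glasso_k < 2:
            raise ValueError("fold counts must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bn_whitelist"] = [list(a) for a in self.bn_whitelist]
        d["bn_blacklist"] = [list(a) for a in self.bn_blacklist]
        return d

    def stage_seed(self, stage: int) -> int:
        ss = np.random.SeedSequence((int(self.seed), int(stage)))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class FittedModel:
    selected_groups: tuple[str, ...]
    net: bnmod.BayesNet
    lam: float


def fit_predictive_model(
    coded: pd.DataFrame, config: PipelineConfig, seed: int | None = None
) -> FittedModel:
    """Variable selection (gLASSO) then BN structure + parameter learning,
    all on the given (training) data only."""
    seed = config.stage_seed(2) if seed is None else seed
    complete = coded.dropna(subset=list(PREDICTORS) + ["aki"])
    design = build_design(complete, list(PREDICTORS))
    if config.glasso_selection == "cv":
        cv = cv_lambda(design, k=config.glasso_k, seed=config.stage_seed(1),
                       n_lambda=config.glasso_n_lambda,
                       lambda_min_ratio=config.glasso_lambda_min_ratio)
        lam, groups = cv.lambda_min, cv.selected_groups
    else:
        path = fit_path(design, n_lambda=config.glasso_n_lambda,
                        lambda_min_ratio=config.glasso_lambda_min_ratio)
        lam, groups, _ = select_ic(path, config.glasso_criterion)
    nodes = list(groups) + ["aki"]
    if len(nodes) < 2:          # degenerate selection: intercept-only model
        dag = bnmod.DAG({"aki": CODED_LEVELS["aki"]}, {"aki": ()})
        net = bnmod.fit_cpts(dag, complete[["aki"]], smoothing=config.bn_smoothing)
        return FittedModel((), net, lam)
    levels = {v: CODED_LEVELS[v] for v in nodes}
    dag = bnmod.tabu_learn(
        complete[nodes], levels,
        bnmod.TabuConfig(
            tabu_len=config.bn_tabu_len, max_iter=config.bn_max_iter,
            restarts=config.bn_restarts, seed=seed,
            whitelist=config.bn_whitelist, blacklist=config.bn_blacklist,
        ),
    )
    net = bnmod.fit_cpts(dag, complete, smoothing=config.bn_smoothing)
    return FittedModel(tuple(groups), net, lam)


def predict_model(model: FittedModel, coded: pd.DataFrame, seed: int = 0) -> np.ndarray:
    return predict_frame(model.net, coded, seed=seed)


def _scenarios_for(net: bnmod.BayesNet) -> tuple[dict, dict]:
    nodes = set(net.dag.nodes)
    abnormal = {k: v for k, v in _WORST.items() if k in nodes}
    corrected = {k: v for k, v in _CORRECTED.items() if k in nodes}
    return abnormal, corrected


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write the artifact bundle into ``outdir``.

    Returns a summary dict (also written as ``summary.json``).  Rerunning
    with the same config produces byte-identical JSON artifacts.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_dict())

    def prov(stage: str, stage_idx: int) -> dict:
        return {"config_hash": chash, "seed": config.seed,
                "stage": stage, "stage_seed": config.stage_seed(stage_idx)}

    # --- stage 0: simulate -------------------------------------------------
    params = CohortParams(
        n_patients=config.n_patients,
        seed=config.stage_seed(0),
        missing_rate=config.missing_rate,
    )
    records = simulate_cohort(params)
    write_cohort_csv(records, out / "cohort.csv")
    write_scr_series_csv(records, out / "scr_series.csv")

    # --- stage 1: eligibility + coding ------------------------------------
    if config.apply_eligibility_filters:
        eligible, exclusions = apply_eligibility(records)
    else:
        eligible, exclusions = list(records), {}
    coded = code_cohort(eligible)
    write_coded_csv(coded, out / "coded.csv")
    write_json({"bands": data_dictionary()}, out / "data_dictionary.json",
               provenance=prov("code", 0))
    write_json({"exclusions": exclusions, "n_eligible": len(eligible)},
               out / "exclusions.json", provenance=prov("code", 0))

    # --- stage 2: univariate statistics ------------------------------------
    report = table1_report(coded)
    report_to_frame(report).to_csv(out / "table1_report.csv", index=False)
    with open(out / "table1_report.json", "w", encoding="utf-8") as fh:
        fh.write(report_to_json(report))

    # --- stage 3: gLASSO path + selection ----------------------------------
    complete = coded.dropna(subset=list(PREDICTORS) + ["aki"])
    design = build_design(complete, list(PREDICTORS))
    path = fit_path(design, n_lambda=config.glasso_n_lambda,
                    lambda_min_ratio=config.glasso_lambda_min_ratio)
    path.to_frame().to_csv(out / "glasso_path.csv", index=False)
    lam_ic, groups_ic, _ = select_ic(path, config.glasso_criterion)
    cv = cv_lambda(design, k=config.glasso_k, seed=config.stage_seed(1),
                   n_lambda=config.glasso_n_lambda,
                   lambda_min_ratio=config.glasso_lambda_min_ratio)
    if config.glasso_selection == "cv":
        lam_sel, groups_sel = cv.lambda_min, cv.selected_groups
    else:
        lam_sel, groups_sel = lam_ic, groups_ic
    write_json(
        {
            "criterion": config.glasso_criterion,
            "lambda_ic": lam_ic, "groups_ic": list(groups_ic),
            "lambda_min_cv": cv.lambda_min,
            "groups_cv": list(cv.selected_groups),
            "cv_error": cv.cv_error, "lambdas": cv.lambdas,
            "selection_mode": config.glasso_selection,
            "lambda_selected": lam_sel, "groups_selected": list(groups_sel),
            "n_complete": design.n, "n_dropped": design.n_dropped,
        },
        out / "glasso_selection.json", provenance=prov("glasso", 1),
    )

    # --- stage 4: Bayesian network -----------------------------------------
    model = fit_predictive_model(coded, config)
    with open(out / "network.json", "w", encoding="utf-8") as fh:
        fh.write(bnmod.net_to_json(model.net))
    bnmod.write_bif(model.net, out / "network.bif")
    # AKI conditional table in the published layout: eGFR x Hb x sodium
    cpd_parents = [p for p in ("egfr_band", "hb_low", "sodium_band")]
    cpd_levels = {v: CODED_LEVELS[v] for v in cpd_parents + ["aki"]}
    cpd_dag = bnmod.DAG(cpd_levels, {"aki": tuple(cpd_parents)})
    cpd_net = bnmod.fit_cpts(cpd_dag, complete, smoothing=config.bn_smoothing)
    bnmod.cpd_table(cpd_net, "aki").to_csv(out / "cpd_aki.csv", index=False)

    # --- stage 5: scenario inference ---------------------------------------
    abnormal, corrected = _scenarios_for(model.net)
    scen = bnmod.scenario_inference(
        model.net, [abnormal, corrected], query="aki",
        n_samples=config.scenario_samples, seed=config.stage_seed(3),
    )
    write_json(
        {"scenarios": [
            {"name": name, **res}
            for name, res in zip(("abnormal_labs", "corrected_labs"), scen)
        ]},
        out / "scenarios.json", provenance=prov("scenarios", 3),
    )

    # --- stage 6: evaluation ------------------------------------------------
    labels = (coded["aki"] == "yes").to_numpy().astype(int)
    bn_scores = predict_frame(model.net, coded, seed=config.stage_seed(4))
    bn_roc = auc(bn_scores, labels, ci_method=config.ci_method)
    base_predictors = model.selected_groups or PREDICTORS
    logit_model, logit_roc, _ = logistic_baseline(coded, base_predictors)
    cvrep = crossvalidate(
        coded,
        fit_fn=lambda train: fit_predictive_model(train, config),
        predict_fn=lambda m, test: predict_model(m, test, seed=config.stage_seed(4)),
        k=config.eval_k, seed=config.stage_seed(4),
        full_scores=bn_scores, full_roc=bn_roc,
    )
    pd.DataFrame(
        {"threshold": bn_roc.thresholds, "sensitivity": bn_roc.sensitivity,
         "specificity": bn_roc.specificity}
    ).to_csv(out / "roc_points.csv", index=False)
    evaluation = {
        "bn_auc": bn_roc.auc, "bn_auc_ci": [bn_roc.ci_low, bn_roc.ci_high],
        "logistic_auc": logit_roc.auc,
        "logistic_auc_ci": [logit_roc.ci_low, logit_roc.ci_high],
        "logistic_model": logit_model,
        "cv_auc": cvrep.pooled.auc,
        "cv_auc_ci": [cvrep.pooled.ci_low, cvrep.pooled.ci_high],
        "cv_fold_aucs": cvrep.fold_aucs,
        "cv_vs_full_p": cvrep.p_value_vs_full,
        "cv_comparison_note": cvrep.comparison_note,
    }
    write_json(evaluation, out / "evaluation.json", provenance=prov("evaluate", 4))

    summary = {
        "n_simulated": len(records),
        "n_eligible": len(eligible),
        "exclusions": exclusions,
        "aki_incidence_pct": 100.0 * float(labels.mean()),
        "lambda_selected": lam_sel,
        "groups_selected": list(groups_sel),
        "bn_nodes": list(model.net.dag.nodes),
        "bn_arcs": [list(a) for a in model.net.dag.arcs],
        "aki_parents": list(model.net.dag.parents.get("aki", ())),
        "scenario_abnormal_p_aki": scen[0]["p_positive"],
        "scenario_corrected_p_aki": scen[1]["p_positive"],
        **{k: v for k, v in evaluation.items()
           if k in ("bn_auc", "logistic_auc", "cv_auc", "cv_vs_full_p")},
    }
    write_json(summary, out / "summary.json", provenance=prov("summary", 5))
    return summary
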
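"""Synthetic hematologic-malignancy inpatient cohorts.

The generator emulates the published cohort's *marginal* structure — 2395
admissions, 15.4% AKI, and the per-variable category frequencies of the
printed risk-factor table — on top of a known ground-truth dependency graph:

    hm_category -> hb_low            (malignancy drives anemia)
    hm_category -> egfr_band         (malignancy drives renal function)
    diabetes    -> egfr_band
    {age_band, hb_low, egfr_band, sodium_band, potassium_band} -> aki

All remaining variables are independent roots.  Child-node conditional
tables are logistic (binary) or cumulative-logit (ordinal) in the parent
levels, with intercepts calibrated by 1-D root finding so the implied
marginals match the printed frequencies exactly.  Dependence strengths are
free parameters of the generator (the source cohort reports none); the
defaults are strong, monotone effects so that graph- and group-recovery
experiments have a well-defined signal.

SCr trajectories are built to be consistent with the sampled AKI label:
AKI-destined patients get a rise of >= 1.5-fold from baseline inside a 48 h
window (the fold multiplier encodes the intended stage), everyone else gets
jitter bounded well below both KDIGO clauses.

The module also ships the printed risk-factor table verbatim as a fixture
(:func:`table1_fixture`), including the reference-group rows that the print
layout leaves implicit (derived by subtraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .bn import DAG, BayesNet, sample_frame
from .coding import CODED_LEVELS, REFERENCE_LEVELS
from .epi import ContingencyTable, ORDINAL_VARIABLES

__all__ = [
    "CohortParams",
    "PatientRecord",
    "simulate_cohort",
    "simulate_coded",
    "truth_net",
    "table1_fixture",
    "fixture_to_json",
    "TRUTH_DAG_EDGES",
    "AKI_PARENTS",
]

# ---------------------------------------------------------------------------
# printed risk-factor table (counts verbatim; reference rows derived by
# subtraction from the printed totals, e.g. normokalemia total
# 2395-333-24 = 2038 with 370-122-20 = 228 AKI cases)
# ---------------------------------------------------------------------------

_TABLE1: dict[str, list[tuple[str, int, int]]] = {
    "age_band": [("<=29", 57, 156), ("30~49", 78, 461),
                 ("50~69", 172, 1064), (">=70", 63, 344)],
    "gender": [("male", 184, 1191), ("female", 186, 834)],
    "hypertension": [("no", 295, 1627), ("yes", 75, 398)],
    "diabetes": [("no", 211, 1370), ("yes", 159, 655)],
    "hm_category": [("lymphoma", 261, 1680), ("leukemia", 48, 153),
                    ("multiple_myeloma", 61, 192)],
    "admission_type": [("normal", 329, 1903), ("emergent", 41, 122)],
    "treatment": [("untreated_palliative", 23, 286),
                  ("chemotherapy", 334, 1702), ("ASCT", 13, 37)],
    "alt_high": [("no", 335, 1910), ("yes", 35, 115)],
    "ast_high": [("no", 308, 1817), ("yes", 62, 208)],
    "tbil_high": [("no", 353, 1952), ("yes", 17, 73)],
    "scr_high": [("no", 291, 1991), ("yes", 79, 34)],
    "egfr_band": [(">=90", 170, 1480), ("60~89", 110, 486), ("<=59", 90, 57)],
    "sua_band": [("<=359", 198, 1421), ("360~420", 58, 340),
                 ("421~480", 40, 160), (">=481", 74, 104)],
    "albumin_low": [("no", 214, 1597), ("yes", 156, 428)],
    "hb_low": [("no", 73, 984), ("yes", 297, 1041)],
    "wbc_high": [("no", 268, 1721), ("yes", 102, 304)],
    "sodium_band": [("hypo", 135, 190), ("normal", 220, 1809),
                    ("hyper", 15, 26)],
    "potassium_band": [("hypo", 122, 211), ("normal", 228, 1810),
                       ("hyper", 20, 4)],
}

COHORT_N = 2395
AKI_N = 370

AKI_PARENTS = ("age_band", "hb_low", "egfr_band", "sodium_band", "potassium_band")
TRUTH_DAG_EDGES: tuple[tuple[str, str], ...] = (
    ("hm_category", "hb_low"),
    ("hm_category", "egfr_band"),
    ("diabetes", "egfr_band"),
) + tuple((p, "aki") for p in AKI_PARENTS)

# default dependence strengths (log-odds); abnormal levels carry positive
# effects so AKI risk is monotone in lab abnormality
_HB_EFFECTS = {"lymphoma": 0.0, "leukemia": 0.9, "multiple_myeloma": 1.1}
_EGFR_HM_EFFECTS = {"lymphoma": 0.0, "leukemia": 0.7, "multiple_myeloma": 1.0}
_EGFR_DIABETES_EFFECT = 0.8
_AKI_EFFECTS = {
    "age_band": {"<=29": 1.2, "30~49": 0.0, "50~69": 0.5, ">=70": 1.0},
    "hb_low": {"no": 0.0, "yes": 1.6},
    "egfr_band": {">=90": 0.0, "60~89": 0.9, "<=59": 2.6},
    "sodium_band": {"hypo": 1.8, "normal": 0.0, "hyper": 1.5},
    "potassium_band": {"hypo": 1.5, "normal": 0.0, "hyper": 2.2},
}

# observed AKI stage mix: 308 / 41 / 21 of 370
_STAGE_PROBS = (308 / 370, 41 / 370, 21 / 370)

# uniform lab value ranges per coded band (units as in the record schema)
_LAB_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "ALT": {"no": (8, 39), "yes": (40, 200)},
    "AST": {"no": (10, 34), "yes": (35, 180)},
    "TBiL": {"no": (5, 20.3), "yes": (20.4, 80)},
    "eGFR": {">=90": (90, 130), "60~89": (60, 89.9), "<=59": (15, 59.9)},
    "SUA": {"<=359": (150, 359), "360~420": (360, 420),
            "421~480": (421, 480), ">=481": (481, 700)},
    "albumin": {"no": (35, 50), "yes": (20, 34.9)},
    "hemoglobin": {"no": (115, 160), "yes": (60, 114.9)},
    "WBC": {"no": (3, 9.4), "yes": (9.5, 40)},
    "sodium": {"hypo": (125, 136.5), "normal": (137, 147.4),
               "hyper": (148, 160)},
    "potassium": {"hypo": (2.5, 3.45), "normal": (3.5, 5.3),
                  "hyper": (5.35, 7.0)},
}
_AGE_RANGES = {"<=29": (18, 29), "30~49": (30, 49), "50~69": (50, 69),
               ">=70": (70, 90)}


def _default_marginals() -> dict[str, dict[str, float]]:
    out = {}
    for var, rows in _TABLE1.items():
        total = sum(a + b for _, a, b in rows)
        out[var] = {lev: (a + b) / total for lev, a, b in rows}
    out["aki"] = {"no": 1 - AKI_N / COHORT_N, "yes": AKI_N / COHORT_N}
    return out


@dataclass(frozen=True)
class PatientRecord:
    """One hospital admission: demographics, comorbidities, admission labs
    and the serum-creatinine time series."""

    patient_id: str
    age_years: float
    gender: str
    hypertension: bool
    diabetes: bool
    hm_category: str
    admission_type: str
    treatment: str
    dialysis_or_rrt_at_baseline: bool
    labs: dict[str, float | None]
    scr_series: tuple[tuple[float, float], ...]
    los_hours: float

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError("age must be nonnegative")
        if self.los_hours < 0:
            raise ValueError("length of stay must be nonnegative")
        times = [t for t, _ in self.scr_series]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("scr_series times must be strictly increasing")
        for name, val in self.labs.items():
            if val is not None and not (val > 0 or np.isnan(val)):
                raise ValueError(f"lab {name} must be positive when present")


@dataclass
class CohortParams:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the published cohort's size, marginal frequencies and
    stage mix; ``truth_cpts`` is calibrated on demand when left ``None``.
    """

    n_patients: int = COHORT_N
    seed: int = 0
    marginal_probs: dict[str, dict[str, float]] = field(default_factory=_default_marginals)
    truth_dag: tuple[tuple[str, str], ...] = TRUTH_DAG_EDGES
    truth_cpts: dict[str, np.ndarray] | None = None
    scr_baseline_range: tuple[float, float] = (45.0, 100.0)
    scr_high_range: tuple[float, float] = (120.0, 300.0)
    aki_scr_multiplier_range: tuple[float, float] = (1.55, 4.0)
    stage_probs: tuple[float, float, float] = _STAGE_PROBS
    missing_rate: float = 0.0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        for var, probs in self.marginal_probs.items():
            s = sum(probs.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(
                    f"marginal probabilities for variable {var!r} sum to {s}, not 1"
                )
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative probability for variable {var!r}")
        # truth DAG acyclicity is enforced by the DAG constructor
        levels = {v: CODED_LEVELS[v] for v in self.node_order()}
        parents: dict[str, tuple[str, ...]] = {v: () for v in levels}
        for u, v in self.truth_dag:
            parents[v] = parents[v] + (u,)
        DAG(levels, parents)
        if self.truth_cpts is not None:
            for node, cpt in self.truth_cpts.items():
                rows = np.asarray(cpt, dtype=float).reshape(-1, len(CODED_LEVELS[node]))
                if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                    raise ValueError(f"truth CPT rows for {node!r} do not sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.aki_scr_multiplier_range
        if lo < 1.5:
            raise ValueError("AKI multiplier range must start at >= 1.5")

    def node_order(self) -> list[str]:
        order = [v for v in CODED_LEVELS if v not in ("aki", "aki_stage")]
        return order + ["aki"]


# ---------------------------------------------------------------------------
# ground-truth network construction (marginal-calibrated)
# ---------------------------------------------------------------------------

def _calibrate_binary(target: float, parent_probs: np.ndarray, effects: np.ndarray) -> float:
    """Intercept c with sum_k w_k * sigmoid(c + e_k) = target."""
    f = lambda c: float(np.sum(parent_probs * expit(c + effects)) - target)
    return brentq(f, -30, 30, xtol=1e-12)


def truth_net(params: CohortParams | None = None) -> BayesNet:
    """Ground-truth generative network over the coded variables.

    Root nodes carry the printed marginal frequencies; child nodes carry
    logistic / cumulative-logit tables whose intercepts are solved so the
    implied marginals match the targets.
    """
    params = params or CohortParams()
    params.validate()
    order = params.node_order()
    levels = {v: tuple(CODED_LEVELS[v]) for v in order}
    parents: dict[str, tuple[str, ...]] = {v: () for v in order}
    for u, v in params.truth_dag:
        parents[v] = parents[v] + (u,)
    dag = DAG(levels, parents)
    if params.truth_cpts is not None:
        return BayesNet(dag, dict(params.truth_cpts))
    if params.truth_dag != TRUTH_DAG_EDGES:
        raise ValueError(
            "truth_cpts must be supplied explicitly for a non-default truth DAG"
        )
    m = params.marginal_probs
    cpts: dict[str, np.ndarray] = {}
    for v in order:
        if not parents[v]:
            cpts[v] = np.array([m[v][lv] for lv in levels[v]], dtype=float)

    hm_p = cpts["hm_category"]
    dm_p = cpts["diabetes"]

    # hb_low | hm_category  (logistic)
    hb_eff = np.array([_HB_EFFECTS[h] for h in levels["hm_category"]])
    c_hb = _calibrate_binary(m["hb_low"]["yes"], hm_p, hb_eff)
    p_yes = expit(c_hb + hb_eff)
    cpts["hb_low"] = np.stack([1 - p_yes, p_yes], axis=-1)

    # egfr_band | hm_category, diabetes  (cumulative logit, severity order)
    e_hm = np.array([_EGFR_HM_EFFECTS[h] for h in levels["hm_category"]])
    e_dm = np.array([0.0, _EGFR_DIABETES_EFFECT])
    eff = e_hm[:, None] + e_dm[None, :]            # (hm, diabetes)
    w = hm_p[:, None] * dm_p[None, :]
    t1 = brentq(lambda c: float(np.sum(w * expit(c - eff))) - m["egfr_band"][">=90"],
                -30, 30, xtol=1e-12)
    t2 = brentq(lambda c: float(np.sum(w * expit(c - eff)))
                - (m["egfr_band"][">=90"] + m["egfr_band"]["60~89"]),
                -30, 30, xtol=1e-12)
    s1, s2 = expit(t1 - eff), expit(t2 - eff)
    cpts["egfr_band"] = np.stack([s1, s2 - s1, 1 - s2], axis=-1)

    # aki | age_band, hb_low, egfr_band, sodium_band, potassium_band
    eff_arrays = [
        np.array([_AKI_EFFECTS[p][lv] for lv in levels[p]]) for p in AKI_PARENTS
    ]
    total_eff = np.zeros([len(levels[p]) for p in AKI_PARENTS])
    for axis, e in enumerate(eff_arrays):
        shape = [1] * len(AKI_PARENTS)
        shape[axis] = len(e)
        total_eff = total_eff + e.reshape(shape)
    # joint parent weights: age, Na, K are roots; (hb, egfr) are dependent
    # through hm_category and diabetes -> enumerate the small ancestor joint
    hb_egfr = np.einsum(
        "h,d,hb,hde->be",
        hm_p, dm_p, cpts["hb_low"], cpts["egfr_band"],
    )
    weights = np.einsum(
        "a,be,s,k->abesk",
        cpts["age_band"], hb_egfr, cpts["sodium_band"], cpts["potassium_band"],
    )
    target = m["aki"]["yes"]
    c_aki = brentq(
        lambda c: float(np.sum(weights * expit(c + total_eff))) - target,
        -30, 30, xtol=1e-12,
    )
    p_aki = expit(c_aki + total_eff)
    cpts["aki"] = np.stack([1 - p_aki, p_aki], axis=-1)

    # dag parent order must match CPT axis order for aki
    parents["aki"] = AKI_PARENTS
    dag = DAG(levels, parents)
    return BayesNet(dag, cpts)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_coded(params: CohortParams | None = None) -> pd.DataFrame:
    """Sample the coded (categorical) cohort table directly from the
    ground-truth network, including the sampled AKI stage."""
    params = params or CohortParams()
    net = truth_net(params)
    rng = np.random.default_rng(params.seed)
    frame = sample_frame(net, params.n_patients, rng)
    stages = np.zeros(len(frame), dtype=int)
    is_aki = (frame["aki"] == "yes").to_numpy() if len(frame) else np.array([], bool)
    n_aki = int(is_aki.sum())
    if n_aki:
        stages[is_aki] = rng.choice([1, 2, 3], size=n_aki, p=params.stage_probs)
    frame["aki_stage"] = stages.astype(str)
    return frame


def _scr_series(
    rng: np.random.Generator,
    baseline: float,
    stage: int,
    mult_range: tuple[float, float],
) -> tuple[tuple[float, float], ...]:
    times = (2.0, 26.0, 50.0, 74.0, 98.0)
    if stage == 0:
        jitter = min(0.09 * baseline, 12.0)
        vals = baseline + rng.uniform(-jitter, jitter, size=len(times))
        vals[0] = baseline
    else:
        lo, hi = mult_range
        stage_ranges = {
            1: (max(lo, 1.55), 1.95),
            2: (2.05, 2.90),
            3: (3.05, max(hi, 3.10)),
        }
        f = rng.uniform(*stage_ranges[stage])
        vals = np.array([
            baseline,
            baseline * (1 + 0.05 * rng.random()),
            baseline * f,                       # peak inside the 48 h window
            baseline * (1 + 0.5 * (f - 1)),
            baseline * (1 + 0.1 * rng.random()),
        ])
    return tuple(zip(times, np.round(vals, 1)))


def simulate_cohort(params: CohortParams | None = None) -> list[PatientRecord]:
    """Generate ``n_patients`` admission records.

    Continuous labs are drawn uniformly inside the sampled category's band,
    so re-coding a simulated record reproduces the sampled categories; the
    SCr series is constructed to trigger (or avoid) the KDIGO criteria
    according to the sampled AKI label.
    """
    params = params or CohortParams()
    coded = simulate_coded(params)
    # independent stream for the continuous layer, so the categorical draw
    # is unchanged by lab-level options
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    records: list[PatientRecord] = []
    for i, (_, row) in enumerate(coded.iterrows()):
        age = int(rng.integers(*_AGE_RANGES[row["age_band"]], endpoint=True))
        labs: dict[str, float | None] = {}
        for lab, bands in _LAB_RANGES.items():
            col = {
                "ALT": "alt_high", "AST": "ast_high", "TBiL": "tbil_high",
                "eGFR": "egfr_band", "SUA": "sua_band",
                "albumin": "albumin_low", "hemoglobin": "hb_low",
                "WBC": "wbc_high", "sodium": "sodium_band",
                "potassium": "potassium_band",
            }[lab]
            lo, hi = bands[row[col]]
            labs[lab] = float(np.round(rng.uniform(lo, hi), 1))
        if row["scr_high"] == "yes":
            baseline = float(np.round(rng.uniform(*params.scr_high_range), 1))
        else:
            baseline = float(np.round(rng.uniform(*params.scr_baseline_range), 1))
        labs["SCr"] = baseline
        stage = int(row["aki_stage"])
        series = _scr_series(rng, baseline, stage, params.aki_scr_multiplier_range)
        if params.missing_rate > 0:
            for lab in list(labs):
                if lab != "SCr" and rng.random() < params.missing_rate:
                    labs[lab] = None
        records.append(
            PatientRecord(
                patient_id=f"P{i:05d}",
                age_years=age,
                gender=row["gender"],
                hypertension=row["hypertension"] == "yes",
                diabetes=row["diabetes"] == "yes",
                hm_category=row["hm_category"],
                admission_type=row["admission_type"],
                treatment=row["treatment"],
                dialysis_or_rrt_at_baseline=False,
                labs=labs,
                scr_series=series,
                los_hours=float(np.round(rng.uniform(120, 480), 1)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# printed-table fixture
# ---------------------------------------------------------------------------

def table1_fixture() -> dict[str, ContingencyTable]:
    """The printed risk-factor table as contingency tables, counts verbatim."""
    out = {}
    for var, rows in _TABLE1.items():
        out[var] = ContingencyTable(
            exposure_levels=tuple(lev for lev, _, _ in rows),
            counts={lev: (a, b) for lev, a, b in rows},
            reference_level=REFERENCE_LEVELS[var],
            ordinal=var in ORDINAL_VARIABLES,
        )
    return out


def fixture_to_json() -> str:
    payload = {
        var: {
            "levels": list(t.exposure_levels),
            "reference": t.reference_level,
            "ordinal": t.ordinal,
            "counts": {l: list(t.counts[l]) for l in t.exposure_levels},
        }
        for var, t in table1_fixture().items()
    }
    return json.dumps(payload, indent=2, sort_keys=True)
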
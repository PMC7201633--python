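"""Eligibility filtering, KDIGO AKI detection/staging and clinical
discretization of admission records into the categorical analysis table.

AKI is detected from the serum-creatinine (SCr) time series alone, using the
two KDIGO creatinine clauses:

* **delta48h** — an absolute SCr increase >= 0.3 mg/dL (26.5 umol/L) between
  any two measurements at most 48 h apart;
* **fold7d** — an SCr value >= 1.5x the running baseline, where the baseline
  is the minimum SCr observed in the preceding 168 h (7 day) window.

Staging uses the fold change against the same rolling baseline: stage 1 for
1.5 to <2.0-fold (or the delta clause alone), stage 2 for 2.0 to <3.0-fold,
stage 3 for >= 3.0-fold or an absolute SCr >= 4.0 mg/dL (353.6 umol/L) once
AKI has been triggered.  Urine-output criteria are not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AKIStatus",
    "detect_aki",
    "apply_eligibility",
    "code_cohort",
    "CODED_LEVELS",
    "REFERENCE_LEVELS",
    "EXCLUSION_REASONS",
    "data_dictionary",
]

# unit conversions: the cohort stores SCr in umol/L (1 mg/dL = 88.4 umol/L)
DELTA_THRESHOLD_UMOL = 26.5     # 0.3 mg/dL
STAGE3_ABS_UMOL = 353.6         # 4.0 mg/dL
DELTA_WINDOW_H = 48.0
BASELINE_WINDOW_H = 168.0

# Category vocabulary of the coded cohort.  Level order is the display /
# ordinal order; `REFERENCE_LEVELS` marks the comparison group used for
# odds ratios and dummy coding.
CODED_LEVELS: dict[str, tuple[str, ...]] = {
    "age_band": ("<=29", "30~49", "50~69", ">=70"),
    "gender": ("male", "female"),
    "hypertension": ("no", "yes"),
    "diabetes": ("no", "yes"),
    "hm_category": ("lymphoma", "leukemia", "multiple_myeloma"),
    "admission_type": ("normal", "emergent"),
    "treatment": ("untreated_palliative", "chemotherapy", "ASCT"),
    "alt_high": ("no", "yes"),
    "ast_high": ("no", "yes"),
    "tbil_high": ("no", "yes"),
    "scr_high": ("no", "yes"),
    "egfr_band": (">=90", "60~89", "<=59"),
    "sua_band": ("<=359", "360~420", "421~480", ">=481"),
    "albumin_low": ("no", "yes"),
    "hb_low": ("no", "yes"),
    "wbc_high": ("no", "yes"),
    "sodium_band": ("hypo", "normal", "hyper"),
    "potassium_band": ("hypo", "normal", "hyper"),
    "aki": ("no", "yes"),
    "aki_stage": ("0", "1", "2", "3"),
}

REFERENCE_LEVELS: dict[str, str] = {
    "age_band": "30~49",
    "gender": "male",
    "hypertension": "no",
    "diabetes": "no",
    "hm_category": "lymphoma",
    "admission_type": "normal",
    "treatment": "untreated_palliative",
    "alt_high": "no",
    "ast_high": "no",
    "tbil_high": "no",
    "scr_high": "no",
    "egfr_band": ">=90",
    "sua_band": "<=359",
    "albumin_low": "no",
    "hb_low": "no",
    "wbc_high": "no",
    "sodium_band": "normal",
    "potassium_band": "normal",
}

EXCLUSION_REASONS = ("los_lt_24h", "baseline_rrt", "insufficient_scr")


@dataclass(frozen=True)
class AKIStatus:
    has_aki: bool
    stage: int
    trigger_time_hours: float | None
    trigger_rule: str  # "delta48h", "fold7d" or "none"

    def __post_init__(self):
        if self.has_aki != (self.stage >= 1):
            raise ValueError("has_aki must agree with stage >= 1")
        if self.has_aki != (self.trigger_time_hours is not None):
            raise ValueError("trigger_time present iff AKI")


def detect_aki(series: Sequence[tuple[float, float]]) -> AKIStatus:
    """Apply both KDIGO creatinine clauses to an SCr series.

    ``series`` is a sequence of ``(time_hours_since_admission, scr_umol_per_L)``
    pairs with strictly increasing times.  The stage is the maximum attained
    over the whole admission; the trigger time is the earliest measurement at
    which either clause fires (the fold clause is reported when both fire
    simultaneously).
    """
    if len(series) < 2:
        raise ValueError("insufficient SCr data: need at least 2 measurements")
    t = np.asarray([p[0] for p in series], dtype=float)
    s = np.asarray([p[1] for p in series], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("SCr series times must be strictly increasing")
    if np.any(s <= 0):
        raise ValueError("SCr values must be positive")

    stage = 0
    trigger_time: float | None = None
    trigger_rule = "none"
    for j in range(1, len(s)):
        # rolling 7-day baseline: minimum SCr in the preceding 168 h
        window = (t[j] - t[:j] <= BASELINE_WINDOW_H)
        fold = s[j] / s[:j][window].min() if window.any() else 0.0
        # 48 h absolute-delta clause against any prior value in window
        recent = (t[j] - t[:j] <= DELTA_WINDOW_H)
        delta_hit = recent.any() and (s[j] - s[:j][recent].min()) >= DELTA_THRESHOLD_UMOL
        fold_hit = fold >= 1.5
        if (delta_hit or fold_hit) and trigger_time is None:
            trigger_time = float(t[j])
            trigger_rule = "fold7d" if fold_hit else "delta48h"
        if fold_hit or delta_hit:
            if fold >= 3.0:
                stage = max(stage, 3)
            elif fold >= 2.0:
                stage = max(stage, 2)
            else:
                stage = max(stage, 1)
    if stage >= 1 and s.max() >= STAGE3_ABS_UMOL:
        stage = 3
    return AKIStatus(
        has_aki=stage >= 1,
        stage=stage,
        trigger_time_hours=trigger_time,
        trigger_rule=trigger_rule,
    )


def apply_eligibility(cohort: Iterable) -> tuple[list, dict[str, int]]:
    """Apply the cohort eligibility filters.

    Exclusions, tallied in fixed order (first matching reason wins):
    hospitalized < 24 h, dialysis/RRT at baseline, fewer than two SCr tests.
    """
    log = {r: 0 for r in EXCLUSION_REASONS}
    eligible = []
    for rec in cohort:
        if rec.los_hours < 24.0:
            log["los_lt_24h"] += 1
        elif rec.dialysis_or_rrt_at_baseline:
            log["baseline_rrt"] += 1
        elif len(rec.scr_series) < 2:
            log["insufficient_scr"] += 1
        else:
            eligible.append(rec)
    return eligible, log


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _band_age(age: float) -> str:
    if age < 30:
        return "<=29"
    if age < 50:
        return "30~49"
    if age < 70:
        return "50~69"
    return ">=70"


def _band_egfr(x: float) -> str:
    if x >= 90:
        return ">=90"
    if x >= 60:
        return "60~89"
    return "<=59"


def _band_sua(x: float) -> str:
    if x < 360:
        return "<=359"
    if x < 421:
        return "360~420"
    if x < 481:
        return "421~480"
    return ">=481"


def _band_sodium(x: float) -> str:
    if x < 137:
        return "hypo"
    if x < 148:
        return "normal"
    return "hyper"


def _band_potassium(x: float) -> str:
    if x < 3.5:
        return "hypo"
    if x <= 5.3:
        return "normal"
    return "hyper"


# lab name -> (coded column, coding function); thresholds are the printed
# admission-lab cutoffs (>= for "high" markers, < for deficiency markers)
_LAB_CODERS = {
    "ALT": ("alt_high", lambda x: "yes" if x >= 40 else "no"),
    "AST": ("ast_high", lambda x: "yes" if x >= 35 else "no"),
    "TBiL": ("tbil_high", lambda x: "yes" if x >= 20.4 else "no"),
    "SCr": ("scr_high", lambda x: "yes" if x >= 115 else "no"),
    "eGFR": ("egfr_band", _band_egfr),
    "SUA": ("sua_band", _band_sua),
    "albumin": ("albumin_low", lambda x: "yes" if x < 35 else "no"),
    "hemoglobin": ("hb_low", lambda x: "yes" if x < 115 else "no"),
    "WBC": ("wbc_high", lambda x: "yes" if x >= 9.5 else "no"),
    "sodium": ("sodium_band", _band_sodium),
    "potassium": ("potassium_band", _band_potassium),
}


def code_cohort(eligible: Iterable) -> pd.DataFrame:
    """Discretize eligible patient records into the categorical table.

    One row per patient; every cell is a category label or ``pd.NA`` (missing
    labs are marked, never imputed).  Negative lab values raise.
    """
    rows = []
    index = []
    for rec in eligible:
        row: dict[str, object] = {
            "age_band": _band_age(rec.age_years),
            "gender": rec.gender,
            "hypertension": "yes" if rec.hypertension else "no",
            "diabetes": "yes" if rec.diabetes else "no",
            "hm_category": rec.hm_category,
            "admission_type": rec.admission_type,
            "treatment": rec.treatment,
        }
        for lab, (col, fn) in _LAB_CODERS.items():
            val = rec.labs.get(lab)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                row[col] = pd.NA
                continue
            if val < 0:
                raise ValueError(f"negative {lab} value for {rec.patient_id}")
            row[col] = fn(float(val))
        status = detect_aki(rec.scr_series)
        row["aki"] = "yes" if status.has_aki else "no"
        row["aki_stage"] = str(status.stage)
        rows.append(row)
        index.append(rec.patient_id)
    coded = pd.DataFrame(rows, index=pd.Index(index, name="patient_id"),
                         columns=list(CODED_LEVELS))
    return coded


def data_dictionary() -> dict:
    """Band definitions for the JSON sidecar written next to the coded CSV."""
    return {
        "age_band": {"<=29": "age <= 29 yr", "30~49": "30-49 yr",
                     "50~69": "50-69 yr", ">=70": ">= 70 yr"},
        "alt_high": {"yes": "ALT >= 40 U/L"},
        "ast_high": {"yes": "AST >= 35 U/L"},
        "tbil_high": {"yes": "TBiL >= 20.4 umol/L"},
        "scr_high": {"yes": "SCr >= 115 umol/L"},
        "egfr_band": {">=90": ">= 90 mL/min/1.73m2", "60~89": "60-89",
                      "<=59": "<= 59"},
        "sua_band": {"<=359": "<= 359 umol/L", "360~420": "360-420",
                     "421~480": "421-480", ">=481": ">= 481"},
        "albumin_low": {"yes": "albumin < 35 g/L (hypoalbuminemia)"},
        "hb_low": {"yes": "hemoglobin < 115 g/L (anemia)"},
        "wbc_high": {"yes": "WBC >= 9.5 x 10^9/L"},
        "sodium_band": {"hypo": "< 137 mmol/L", "normal": "137-147",
                        "hyper": ">= 148"},
        "potassium_band": {"hypo": "< 3.5 mmol/L", "normal": "3.5-5.3",
                           "hyper": "> 5.3"},
        "aki": {"yes": "KDIGO creatinine criteria met"},
        "aki_stage": {"0": "no AKI", "1": "stage 1", "2": "stage 2",
                      "3": "stage 3"},
        "missing": "empty cell / NA; never imputed",
    }
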
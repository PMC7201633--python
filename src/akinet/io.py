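"""Readers and writers for the pipeline's artifact formats.

CSV dialect: UTF-8, comma separated, header row, "." decimal, missing values
as empty cells.  JSON artifacts carry a ``_provenance`` header (config hash
and stage seed) and are serialized with sorted keys so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synthetic import PatientRecord

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_scr_series_csv",
    "read_scr_series_csv",
    "read_records",
    "write_coded_csv",
    "read_coded_csv",
    "write_json",
    "config_hash",
]

_LAB_COLUMNS = ("ALT", "AST", "TBiL", "SCr", "eGFR", "SUA",
                "albumin", "hemoglobin", "WBC", "sodium", "potassium")
_BOOL_COLUMNS = ("hypertension", "diabetes", "dialysis_or_rrt_at_baseline")


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"failed to parse {path}: {exc}") from exc


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    """One row per patient; labs as columns; missing labs as empty cells."""
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "age_years": r.age_years,
            "gender": r.gender,
            "hypertension": int(r.hypertension),
            "diabetes": int(r.diabetes),
            "hm_category": r.hm_category,
            "admission_type": r.admission_type,
            "treatment": r.treatment,
            "dialysis_or_rrt_at_baseline": int(r.dialysis_or_rrt_at_baseline),
            "los_hours": r.los_hours,
        }
        for lab in _LAB_COLUMNS:
            row[lab] = r.labs.get(lab)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_scr_series_csv(records: Iterable[PatientRecord], path) -> None:
    """Long format: patient_id, time_hours, scr_umol_l."""
    rows = [
        {"patient_id": r.patient_id, "time_hours": t, "scr_umol_l": v}
        for r in records
        for t, v in r.scr_series
    ]
    pd.DataFrame(rows, columns=["patient_id", "time_hours", "scr_umol_l"]).to_csv(
        path, index=False
    )


def read_scr_series_csv(path) -> dict[str, list[tuple[float, float]]]:
    df = _read_csv(path)
    out: dict[str, list[tuple[float, float]]] = {}
    for pid, grp in df.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_hours")
        out[str(pid)] = list(zip(grp["time_hours"].astype(float),
                                 grp["scr_umol_l"].astype(float)))
    return out


def read_cohort_csv(path) -> pd.DataFrame:
    return _read_csv(path)


def read_records(cohort_path, series_path) -> list[PatientRecord]:
    """Join the per-patient table and the SCr series into records."""
    df = read_cohort_csv(cohort_path)
    series = read_scr_series_csv(series_path)
    records = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        labs = {}
        for lab in _LAB_COLUMNS:
            v = row.get(lab)
            labs[lab] = None if pd.isna(v) else float(v)
        records.append(
            PatientRecord(
                patient_id=pid,
                age_years=float(row["age_years"]),
                gender=str(row["gender"]),
                hypertension=bool(int(row["hypertension"])),
                diabetes=bool(int(row["diabetes"])),
                hm_category=str(row["hm_category"]),
                admission_type=str(row["admission_type"]),
                treatment=str(row["treatment"]),
                dialysis_or_rrt_at_baseline=bool(int(row["dialysis_or_rrt_at_baseline"])),
                labs=labs,
                scr_series=tuple(series.get(pid, ())),
                los_hours=float(row["los_hours"]),
            )
        )
    return records


def write_coded_csv(coded: pd.DataFrame, path) -> None:
    coded.to_csv(path, index=True, na_rep="")


def read_coded_csv(path) -> pd.DataFrame:
    df = _read_csv(path)
    if "patient_id" in df.columns:
        df = df.set_index("patient_id")
    if "aki_stage" in df.columns:
        df["aki_stage"] = df["aki_stage"].astype("Int64").astype(str)
    return df


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(payload: Mapping, path, provenance: Mapping | None = None) -> None:
    data = dict(payload)
    if provenance is not None:
        data["_provenance"] = dict(provenance)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, cls=_Encoder)
        fh.write("\n")


def config_hash(config_dict: Mapping) -> str:
    canon = json.dumps(config_dict, sort_keys=True, cls=_Encoder)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
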
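"""Univariate association statistics for the coded cohort table.

Implements the descriptive layer of the analysis: per-variable AKI counts and
percentages, Pearson chi-square tests (no continuity correction), the
Cochran-Mantel-Haenszel linear trend test for ordinal exposures, and crude
odds ratios with Woolf (log-normal) 95% confidence intervals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "ORResult",
    "crude_or",
    "pearson_chi2",
    "cmh_trend",
    "table1_report",
    "report_from_tables",
    "tables_from_coded",
    "ORDINAL_VARIABLES",
]

# Variables whose levels are ordered; these get the CMH trend test, everything
# else gets Pearson chi-square (matching the footnote convention of the
# published risk-factor table).
ORDINAL_VARIABLES = ("age_band", "egfr_band", "sua_band")


@dataclass(frozen=True)
class ContingencyTable:
    """R x 2 cross-tabulation of an exposure against the AKI outcome.

    ``counts`` maps each exposure level to ``(aki_count, non_aki_count)``.
    """

    exposure_levels: tuple[str, ...]
    counts: Mapping[str, tuple[int, int]]
    reference_level: str
    ordinal: bool = False

    def __post_init__(self):
        object.__setattr__(self, "exposure_levels", tuple(self.exposure_levels))
        object.__setattr__(
            self, "counts", {k: (int(a), int(b)) for k, (a, b) in self.counts.items()}
        )
        if set(self.counts) != set(self.exposure_levels):
            raise ValueError("counts keys must match exposure_levels")
        if self.reference_level not in self.exposure_levels:
            raise ValueError(f"reference level {self.reference_level!r} not a level")
        for lev, (a, b) in self.counts.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative count at level {lev!r}")

    @property
    def matrix(self) -> np.ndarray:
        """(R, 2) array in exposure_levels order, columns (AKI, non-AKI)."""
        return np.array([self.counts[l] for l in self.exposure_levels], dtype=float)

    def total(self) -> int:
        return int(self.matrix.sum())

    def aki_total(self) -> int:
        return int(self.matrix[:, 0].sum())


@dataclass(frozen=True)
class ORResult:
    level: str
    odds_ratio: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval does not bracket the OR")


def crude_or(
    table: ContingencyTable, level: str, haldane: bool = False
) -> ORResult:
    """Crude odds ratio of ``level`` versus the table's reference level.

    OR = (a*d)/(b*c) with a, b the AKI / non-AKI counts at ``level`` and
    c, d those at the reference.  The 95% CI is Woolf's log-normal interval
    ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.  Zero cells raise
    unless ``haldane`` adds the 0.5 Haldane-Anscombe correction.
    """
    if level == table.reference_level:
        raise ValueError("level equals the reference level")
    a, b = table.counts[level]
    c, d = table.counts[table.reference_level]
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        if not haldane:
            raise ValueError(
                "zero cell in 2x2 table; pass haldane=True for the "
                "Haldane-Anscombe 0.5 correction"
            )
        cells = cells + 0.5
    a, b, c, d = cells
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ORResult(
        level=level,
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - 1.96 * se)),
        ci_high=float(np.exp(np.log(orr) + 1.96 * se)),
    )


def pearson_chi2(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square on the R x 2 table, no continuity correction."""
    obs = table.matrix
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 exposure levels")
    expected = stats.contingency.expected_freq(obs)
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    stat, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


def cmh_trend(table: ContingencyTable) -> tuple[float, int, float]:
    """Cochran-Mantel-Haenszel linear trend statistic for ordered exposures.

    Uses integer scores 1..K on the exposure levels; the statistic is the
    Mantel-Haenszel correlation form (N - 1) * r^2 where r is the Pearson
    correlation between exposure score and the binary outcome, referred to a
    chi-square distribution with 1 df.
    """
    if not table.ordinal:
        raise ValueError("CMH trend requires an ordinal table")
    obs = table.matrix
    k = obs.shape[0]
    if k < 3:
        raise ValueError("need at least 3 ordered levels")
    n = obs.sum()
    scores = np.arange(1, k + 1, dtype=float)
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    mean_s = np.sum(scores * row_tot) / n
    # outcome coded 1 for AKI, 0 otherwise
    mean_y = col_tot[0] / n
    cov = np.sum(obs[:, 0] * (scores - mean_s)) * (1 - mean_y) / n - np.sum(
        obs[:, 1] * (scores - mean_s)
    ) * mean_y / n
    var_s = np.sum(row_tot * (scores - mean_s) ** 2) / n
    var_y = mean_y * (1 - mean_y)
    if var_s == 0 or var_y == 0:
        return 0.0, 1, 1.0
    r = cov / np.sqrt(var_s * var_y)
    stat = (n - 1) * r * r
    return float(stat), 1, float(stats.chi2.sf(stat, 1))


# ---------------------------------------------------------------------------
# whole-table report
# ---------------------------------------------------------------------------

@dataclass
class VariableReport:
    variable: str
    table: ContingencyTable
    percents: dict[str, float]
    test: str  # "pearson", "cmh" or "skipped"
    statistic: float | None
    df: int | None
    p_value: float | None
    odds_ratios: dict[str, ORResult]
    note: str = ""


def _report_variable(name: str, table: ContingencyTable) -> VariableReport:
    percents = {}
    for lev in table.exposure_levels:
        a, b = table.counts[lev]
        percents[lev] = 100.0 * a / (a + b) if a + b else float("nan")
    observed_levels = [l for l in table.exposure_levels if sum(table.counts[l]) > 0]
    degenerate = len(observed_levels) < 2 or table.aki_total() in (0, table.total())
    if degenerate:
        return VariableReport(
            name, table, percents, "skipped", None, None, None, {},
            note="degenerate table: single observed level or outcome",
        )
    # unobserved levels stay in the counts/percent columns but are dropped
    # from the test statistic (their expected counts are zero)
    test_table = ContingencyTable(
        exposure_levels=tuple(observed_levels),
        counts={l: table.counts[l] for l in observed_levels},
        reference_level=(table.reference_level
                         if table.reference_level in observed_levels
                         else observed_levels[0]),
        ordinal=table.ordinal,
    )
    if test_table.ordinal and len(test_table.exposure_levels) >= 3:
        stat, df, p = cmh_trend(test_table)
        test = "cmh"
    else:
        stat, df, p = pearson_chi2(test_table)
        test = "pearson"
    ors = {}
    for lev in table.exposure_levels:
        if lev == table.reference_level:
            continue
        try:
            ors[lev] = crude_or(table, lev)
        except ValueError:
            ors[lev] = crude_or(table, lev, haldane=True)
    return VariableReport(name, table, percents, test, stat, df, p, ors)


def report_from_tables(
    tables: Mapping[str, ContingencyTable]
) -> dict[str, VariableReport]:
    """Per-variable statistics from pre-built contingency tables."""
    return {name: _report_variable(name, t) for name, t in tables.items()}


def tables_from_coded(
    coded: pd.DataFrame,
    variables: Mapping[str, Sequence[str]],
    reference_levels: Mapping[str, str],
    outcome: str = "aki",
) -> dict[str, ContingencyTable]:
    """Cross-tabulate each coded variable against the AKI outcome.

    Rows with a missing value in a variable are dropped from that variable's
    table only.
    """
    if coded.empty:
        raise ValueError("coded cohort is empty")
    y = coded[outcome].astype(str) == "yes"
    out = {}
    for var, levels in variables.items():
        col = coded[var]
        counts = {}
        for lev in levels:
            sel = col.astype(str) == str(lev)
            counts[lev] = (int((sel & y).sum()), int((sel & ~y).sum()))
        out[var] = ContingencyTable(
            exposure_levels=tuple(str(l) for l in levels),
            counts=counts,
            reference_level=str(reference_levels[var]),
            ordinal=var in ORDINAL_VARIABLES,
        )
    return out


def table1_report(
    coded: pd.DataFrame,
    variables: Mapping[str, Sequence[str]] | None = None,
    reference_levels: Mapping[str, str] | None = None,
) -> dict[str, VariableReport]:
    """Machine-readable replica of the published risk-factor table layout.

    For an arbitrary coded cohort DataFrame: counts, per-level AKI
    percentages, the appropriate test statistic and crude ORs per variable.
    """
    from .coding import CODED_LEVELS, REFERENCE_LEVELS  # local import, no cycle

    variables = variables or {
        k: v for k, v in CODED_LEVELS.items() if k not in ("aki", "aki_stage")
    }
    reference_levels = reference_levels or REFERENCE_LEVELS
    tables = tables_from_coded(coded, variables, reference_levels)
    return report_from_tables(tables)


def overall_incidence(tables: Mapping[str, ContingencyTable], variable: str = "hm_category") -> float:
    """Overall AKI incidence (%) from any variable's full-cohort table."""
    t = tables[variable]
    return 100.0 * t.aki_total() / t.total()


def report_to_frame(report: Mapping[str, VariableReport]) -> pd.DataFrame:
    rows = []
    for var, rep in report.items():
        for lev in rep.table.exposure_levels:
            a, b = rep.table.counts[lev]
            orr = rep.odds_ratios.get(lev)
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "total": a + b,
                    "aki": a,
                    "aki_pct": rep.percents[lev],
                    "test": rep.test,
                    "statistic": rep.statistic,
                    "p_value": rep.p_value,
                    "odds_ratio": 1.0 if lev == rep.table.reference_level and rep.test != "skipped" else (orr.odds_ratio if orr else None),
                    "ci_low": orr.ci_low if orr else None,
                    "ci_high": orr.ci_high if orr else None,
                }
            )
    return pd.DataFrame(rows)


def report_to_json(report: Mapping[str, VariableReport]) -> str:
    payload = {}
    for var, rep in report.items():
        payload[var] = {
            "levels": list(rep.table.exposure_levels),
            "reference": rep.table.reference_level,
            "counts": {l: list(rep.table.counts[l]) for l in rep.table.exposure_levels},
            "aki_pct": rep.percents,
            "test": rep.test,
            "statistic": rep.statistic,
            "df": rep.df,
            "p_value": rep.p_value,
            "odds_ratios": {
                l: {"or": o.odds_ratio, "ci_low": o.ci_low, "ci_high": o.ci_high}
                for l, o in rep.odds_ratios.items()
            },
            "note": rep.note,
        }
    return json.dumps(payload, indent=2, sort_keys=True)
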
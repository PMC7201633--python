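"""Univariate statistics: crude ORs, Pearson chi-square, CMH trend, and the
full printed-table reproduction from the packaged fixture."""

import numpy as np
import pytest

from akinet.coding import CODED_LEVELS
from akinet.epi import (ContingencyTable, cmh_trend, crude_or, pearson_chi2,
                        report_from_tables, overall_incidence, table1_report)
from akinet.synthetic import CohortParams, simulate_coded, table1_fixture


def _table(rows, ref, ordinal=False):
    return ContingencyTable(
        exposure_levels=tuple(r[0] for r in rows),
        counts={r[0]: (r[1], r[2]) for r in rows},
        reference_level=ref,
        ordinal=ordinal,
    )


# ---------------------------------------------------------------------------
# crude odds ratios
# ---------------------------------------------------------------------------

def test_or_gender_matches_printed_value(fixture_tables):
    res = crude_or(fixture_tables["gender"], "female")
    assert round(res.odds_ratio, 2) == 1.44
    assert round(res.ci_low, 2) == 1.16
    assert round(res.ci_high, 2) == 1.80


def test_or_identical_rows_is_one():
    t = _table([("a", 50, 100), ("b", 50, 100)], ref="a")
    assert crude_or(t, "b").odds_ratio == pytest.approx(1.0)


def test_or_reciprocal_under_reference_swap(fixture_tables):
    t = fixture_tables["diabetes"]
    fwd = crude_or(t, "yes")
    swapped = _table([("yes", *t.counts["yes"]), ("no", *t.counts["no"])], ref="yes")
    rev = crude_or(swapped, "no")
    assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
    assert rev.ci_low == pytest.approx(1 / fwd.ci_high)
    assert rev.ci_high == pytest.approx(1 / fwd.ci_low)


def test_or_zero_cell_suggests_haldane():
    t = _table([("a", 0, 100), ("b", 50, 100)], ref="b")
    with pytest.raises(ValueError, match="Haldane"):
        crude_or(t, "a")
    res = crude_or(t, "a", haldane=True)
    assert 0 < res.odds_ratio < 1


# ---------------------------------------------------------------------------
# Pearson chi-square
# ---------------------------------------------------------------------------

def test_chi2_gender_and_diabetes_match_printed(fixture_tables):
    stat, df, p = pearson_chi2(fixture_tables["gender"])
    assert round(stat, 3) == 10.561 and df == 1 and p < 0.05
    stat, df, _ = pearson_chi2(fixture_tables["diabetes"])
    assert round(stat, 3) == 15.748


def test_chi2_proportional_rows_is_zero():
    t = _table([("a", 10, 90), ("b", 30, 270), ("c", 20, 180)], ref="a")
    stat, df, p = pearson_chi2(t)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 2 and p == pytest.approx(1.0)


def test_chi2_matches_direct_oe_summation_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        obs = rng.integers(1, 200, size=(rng.integers(2, 5), 2)).astype(float)
        rows = [(f"l{i}", int(a), int(b)) for i, (a, b) in enumerate(obs)]
        stat, df, _ = pearson_chi2(_table(rows, ref="l0"))
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum(), abs=1e-10)
        assert df == obs.shape[0] - 1


def test_chi2_2x2_closed_form_and_row_permutation_invariance():
    a, b, c, d = 184, 1191, 186, 834
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    s1, _, _ = pearson_chi2(_table([("m", a, b), ("f", c, d)], ref="m"))
    s2, _, _ = pearson_chi2(_table([("f", c, d), ("m", a, b)], ref="m"))
    assert s1 == pytest.approx(closed, abs=1e-10)
    assert s1 == pytest.approx(s2, abs=1e-12)


# ---------------------------------------------------------------------------
# CMH trend
# ---------------------------------------------------------------------------

def test_cmh_proportional_rows_is_zero():
    t = _table([("a", 10, 90), ("b", 30, 270), ("c", 20, 180)], ref="a",
               ordinal=True)
    stat, df, p = cmh_trend(t)
    assert stat == pytest.approx(0.0, abs=1e-12) and df == 1


def test_cmh_matches_n_minus_1_r_squared_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        obs = rng.integers(5, 150, size=(rng.integers(3, 6), 2))
        rows = [(f"l{i}", int(a), int(b)) for i, (a, b) in enumerate(obs)]
        stat, _, _ = cmh_trend(_table(rows, ref="l0", ordinal=True))
        scores = np.repeat(np.arange(1, obs.shape[0] + 1), obs.sum(1))
        y = np.concatenate([np.repeat([1, 0], row) for row in obs])
        r = np.corrcoef(scores, y)[0, 1]
        assert stat == pytest.approx((obs.sum() - 1) * r * r, abs=1e-9)


def test_cmh_requires_ordinal_table(fixture_tables):
    with pytest.raises(ValueError, match="ordinal"):
        cmh_trend(fixture_tables["gender"])


def test_cmh_sua_matches_printed_value(fixture_tables):
    stat, _, _ = cmh_trend(fixture_tables["sua_band"])
    assert round(stat, 3) == 88.388


# ---------------------------------------------------------------------------
# fixture integrity and full printed-table reproduction
# ---------------------------------------------------------------------------

def test_fixture_tables_sum_to_cohort_totals(fixture_tables):
    """All variables cross-tabulate to 2395 patients / 370 AKI except eGFR,
    whose published rows themselves total 2393 (kept verbatim)."""
    for var, t in fixture_tables.items():
        assert t.aki_total() == 370, var
        assert t.total() == (2393 if var == "egfr_band" else 2395), var


_PRINTED_ORS = [
    ("age_band", "<=29", 2.16), ("age_band", "50~69", 0.96), ("age_band", ">=70", 1.08),
    ("gender", "female", 1.44),
    ("hypertension", "yes", 1.04), ("diabetes", "yes", 1.58),
    ("hm_category", "leukemia", 2.02), ("hm_category", "multiple_myeloma", 2.05),
    ("admission_type", "emergent", 1.94),
    ("treatment", "ASCT", 4.37),
    ("alt_high", "yes", 1.74), ("ast_high", "yes", 1.76), ("tbil_high", "yes", 1.29),
    ("scr_high", "yes", 15.9),
    ("egfr_band", "<=59", 13.75),
    ("sua_band", "360~420", 1.22), ("sua_band", "421~480", 1.79), ("sua_band", ">=481", 5.11),
    ("albumin_low", "yes", 2.72), ("hb_low", "yes", 3.85), ("wbc_high", "yes", 2.15),
    ("sodium_band", "hypo", 5.84), ("sodium_band", "hyper", 4.74),
    ("potassium_band", "hypo", 4.59), ("potassium_band", "hyper", 39.69),
]


@pytest.mark.parametrize("var, level, printed", _PRINTED_ORS)
def test_printed_odds_ratios_reproduced(fixture_tables, var, level, printed):
    res = crude_or(fixture_tables[var], level)
    decimals = len(str(printed).split(".")[1])
    assert round(res.odds_ratio, decimals) == printed


_PRINTED_CHI2 = [
    ("gender", 10.561), ("hypertension", 0.075), ("diabetes", 15.748),
    ("hm_category", 31.429), ("admission_type", 12.610), ("treatment", 20.846),
    ("alt_high", 7.616), ("ast_high", 13.154), ("tbil_high", 0.847),
    ("scr_high", 269.309), ("albumin_low", 75.012), ("hb_low", 105.701),
    ("wbc_high", 35.028), ("sodium_band", 216.335), ("potassium_band", 227.450),
]


@pytest.mark.parametrize("var, printed", _PRINTED_CHI2)
def test_printed_chi_square_reproduced(fixture_tables, var, printed):
    stat, _, _ = pearson_chi2(fixture_tables[var])
    assert round(stat, 3) == printed


def test_report_incidences_match_printed(fixture_tables):
    assert round(overall_incidence(fixture_tables), 1) == 15.4
    rep = report_from_tables(fixture_tables)
    hm = rep["hm_category"].percents
    assert round(hm["multiple_myeloma"], 1) == 24.1
    assert round(hm["leukemia"], 1) == 23.9
    assert round(hm["lymphoma"], 1) == 13.4


def test_report_on_coded_cohort_runs(coded_2000):
    rep = table1_report(coded_2000)
    assert set(rep) == {v for v in CODED_LEVELS if v not in ("aki", "aki_stage")}
    assert rep["egfr_band"].test == "cmh"
    assert rep["gender"].test == "pearson"
    for var, vr in rep.items():
        for lev, o in vr.odds_ratios.items():
            assert o.ci_low <= o.odds_ratio <= o.ci_high


def test_degenerate_outcome_skips_statistics(coded_2000):
    no_aki = coded_2000.copy()
    no_aki["aki"] = "no"
    rep = table1_report(no_aki)
    assert all(vr.test == "skipped" for vr in rep.values())
    assert all(vr.odds_ratios == {} for vr in rep.values())
    assert "degenerate" in rep["gender"].note
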
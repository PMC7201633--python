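"""Discrete Bayesian network: BIC scoring, tabu structure search, ML
parameter learning, and the three inference engines against an enumeration
oracle."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from akinet.bn import (DAG, BayesNet, ImpossibleEvidenceError, TabuConfig,
                       bic_score, cpd_table, fit_cpts, infer_exact,
                       infer_logic_sampling, infer_lw, net_from_json,
                       net_to_json, sample_frame, scenario_inference,
                       skeleton_hamming_distance, tabu_learn, write_bif)
from conftest import make_random_net


@pytest.fixture
def two_node_net():
    lv = {"A": ("0", "1"), "B": ("0", "1")}
    dag = DAG(lv, {"B": ("A",)})
    cpts = {"A": np.array([0.7, 0.3]),
            "B": np.array([[0.9, 0.1], [0.2, 0.8]])}
    return BayesNet(dag, cpts)


# ---------------------------------------------------------------------------
# DAG and scoring
# ---------------------------------------------------------------------------

def test_dag_rejects_cycles_and_self_loops():
    lv = {"A": ("0", "1"), "B": ("0", "1")}
    with pytest.raises(ValueError, match="cycle"):
        DAG(lv, {"A": ("B",), "B": ("A",)})
    with pytest.raises(ValueError, match="self-loop"):
        DAG(lv, {"A": ("A",)})


def test_bic_single_binary_node_closed_form():
    n1, n0 = 60, 40
    data = pd.DataFrame({"A": ["1"] * n1 + ["0"] * n0})
    dag = DAG({"A": ("0", "1")}, {})
    total, per_node = bic_score(dag, data)
    n = n1 + n0
    expected = n1 * np.log(n1 / n) + n0 * np.log(n0 / n) - 0.5 * np.log(n)
    assert total == pytest.approx(expected, abs=1e-10)
    assert per_node["A"] == pytest.approx(expected, abs=1e-10)


def test_bic_decomposes_over_families(coded_2000):
    """Editing one node's parents changes only that node's term."""
    nodes = ["diabetes", "egfr_band", "aki"]
    lv = {n: ("no", "yes") if n != "egfr_band" else (">=90", "60~89", "<=59")
          for n in nodes}
    d0 = DAG(lv, {})
    d1 = DAG(lv, {"egfr_band": ("diabetes",)})
    _, s0 = bic_score(d0, coded_2000)
    _, s1 = bic_score(d1, coded_2000)
    assert s0["diabetes"] == pytest.approx(s1["diabetes"], abs=1e-9)
    assert s0["aki"] == pytest.approx(s1["aki"], abs=1e-9)
    assert s0["egfr_band"] != s1["egfr_band"]


def test_bic_prefers_empty_graph_on_independent_data():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({"A": rng.choice(["0", "1"], 5000),
                         "B": rng.choice(["0", "1"], 5000)})
    lv = {"A": ("0", "1"), "B": ("0", "1")}
    s_empty, _ = bic_score(DAG(lv, {}), data)
    s_arc, _ = bic_score(DAG(lv, {"B": ("A",)}), data)
    assert s_empty >= s_arc


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------

def test_tabu_recovers_chain_skeleton():
    rng = np.random.default_rng(1)
    lv = {"A": ("0", "1"), "B": ("0", "1"), "C": ("0", "1")}
    truth = DAG(lv, {"B": ("A",), "C": ("B",)})
    cpts = {"A": np.array([0.3, 0.7]),
            "B": np.array([[0.9, 0.1], [0.2, 0.8]]),
            "C": np.array([[0.85, 0.15], [0.1, 0.9]])}
    data = sample_frame(BayesNet(truth, cpts), 5000, rng)
    learned = tabu_learn(data, lv, TabuConfig(seed=0))
    assert skeleton_hamming_distance(learned, truth) == 0


def test_tabu_empty_graph_on_independent_columns():
    rng = np.random.default_rng(2)
    data = pd.DataFrame({c: rng.choice(["0", "1"], 4000) for c in "ABCD"})
    lv = {c: ("0", "1") for c in "ABCD"}
    learned = tabu_learn(data, lv, TabuConfig(seed=0))
    assert learned.arcs == ()


def test_tabu_whitelist_forces_arc(coded_2000):
    lv = {"gender": ("male", "female"), "aki": ("no", "yes")}
    learned = tabu_learn(coded_2000[list(lv)], lv,
                         TabuConfig(whitelist=(("gender", "aki"),)))
    assert ("gender", "aki") in learned.arcs


def test_tabu_whitelist_cycle_rejected(coded_2000):
    lv = {"gender": ("male", "female"), "aki": ("no", "yes")}
    with pytest.raises(ValueError, match="cycle"):
        tabu_learn(coded_2000[list(lv)], lv,
                   TabuConfig(whitelist=(("gender", "aki"), ("aki", "gender"))))


def test_tabu_deterministic_given_seed(coded_2000):
    nodes = ["diabetes", "egfr_band", "hb_low", "aki"]
    from akinet.coding import CODED_LEVELS
    lv = {n: CODED_LEVELS[n] for n in nodes}
    a = tabu_learn(coded_2000[nodes], lv, TabuConfig(seed=5))
    b = tabu_learn(coded_2000[nodes], lv, TabuConfig(seed=5))
    assert a.arcs == b.arcs


# ---------------------------------------------------------------------------
# parameter learning
# ---------------------------------------------------------------------------

def test_fit_cpts_rootless_node_relative_frequencies():
    data = pd.DataFrame({"A": ["1"] * 60 + ["0"] * 40})
    net = fit_cpts(DAG({"A": ("0", "1")}, {}), data)
    assert np.allclose(net.cpts["A"], [0.4, 0.6])


def test_fit_cpts_pseudocount_on_unobserved_row_gives_uniform():
    data = pd.DataFrame({"A": ["0"] * 50, "B": ["0"] * 25 + ["1"] * 25})
    dag = DAG({"A": ("0", "1"), "B": ("0", "1")}, {"B": ("A",)})
    net = fit_cpts(dag, data, smoothing=1.0)
    assert np.allclose(net.cpts["B"][1], [0.5, 0.5])   # A=1 never observed


def test_fit_cpts_zero_row_fallback_warns():
    data = pd.DataFrame({"A": ["0"] * 50, "B": ["0"] * 25 + ["1"] * 25})
    dag = DAG({"A": ("0", "1"), "B": ("0", "1")}, {"B": ("A",)})
    with pytest.warns(UserWarning, match="unobserved parent"):
        net = fit_cpts(dag, data)
    assert np.allclose(net.cpts["B"][1], [0.5, 0.5])


def test_aki_cpt_has_18_rows_in_published_layout(coded_2000):
    from akinet.coding import CODED_LEVELS
    parents = ("egfr_band", "hb_low", "sodium_band")
    lv = {v: CODED_LEVELS[v] for v in parents + ("aki",)}
    dag = DAG(lv, {"aki": parents})
    with pytest.warns(UserWarning):
        net = fit_cpts(dag, coded_2000)
    table = cpd_table(net, "aki")
    assert len(table) == 18                       # 3 x 2 x 3 parent states
    pct = table[[c for c in table.columns if c.startswith("P(")]].to_numpy()
    assert np.allclose(pct.sum(axis=1), 100.0)
    # row order follows the parent-configuration product order
    assert list(table["egfr_band"][:6]) == [">=90"] * 6


def test_cpd_table_no_parents_single_row(two_node_net):
    t = cpd_table(two_node_net, "A")
    assert len(t) == 1


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def test_exact_two_node_bayes_rule(two_node_net):
    # P(A=1 | B=1) = .3*.8 / (.3*.8 + .7*.1)
    post = infer_exact(two_node_net, {"B": "1"}, "A")
    assert post["1"] == pytest.approx(0.24 / 0.31, abs=1e-12)


def test_exact_point_mass_on_observed_query(two_node_net):
    assert infer_exact(two_node_net, {"A": "1"}, "A") == {"0": 0.0, "1": 1.0}


def test_exact_no_evidence_matches_brute_force_factorization():
    rng = np.random.default_rng(3)
    for _ in range(10):
        net = make_random_net(rng, n_nodes=4)
        q = net.dag.nodes[rng.integers(4)]
        post = infer_exact(net, {}, q)
        # independent oracle: enumerate the factorized joint with itertools
        marg = {lv: 0.0 for lv in net.dag.levels[q]}
        total = 0.0
        for combo in itertools.product(*[range(net.dag.card(n)) for n in net.dag.nodes]):
            idx = dict(zip(net.dag.nodes, combo))
            p = 1.0
            for n in net.dag.nodes:
                key = tuple(idx[par] for par in net.dag.parents[n]) + (idx[n],)
                p *= net.cpts[n][key]
            total += p
            marg[net.dag.levels[q][idx[q]]] += p
        assert total == pytest.approx(1.0, abs=1e-9)      # global normalization
        for lv in marg:
            assert post[lv] == pytest.approx(marg[lv], abs=1e-9)


def test_exact_impossible_evidence_raises():
    lv = {"A": ("0", "1"), "B": ("0", "1")}
    net = BayesNet(DAG(lv, {"B": ("A",)}),
                   {"A": np.array([1.0, 0.0]),
                    "B": np.array([[1.0, 0.0], [0.5, 0.5]])})
    with pytest.raises(ImpossibleEvidenceError):
        infer_exact(net, {"B": "1"}, "A")


def test_lw_matches_exact_within_3_se():
    rng = np.random.default_rng(8)
    bad = total = 0
    for trial in range(25):
        net = make_random_net(rng)
        q = net.dag.nodes[rng.integers(len(net.dag.nodes))]
        ev = {n: net.dag.levels[n][rng.integers(net.dag.card(n))]
              for n in net.dag.nodes if n != q and rng.random() < 0.4}
        try:
            exact = infer_exact(net, ev, q)
        except ImpossibleEvidenceError:
            continue
        est, se = infer_lw(net, ev, q, n_samples=50_000, seed=trial)
        for lv in exact:
            total += 1
            err = abs(est[lv] - exact[lv])
            bad += err > 3 * max(se[lv], 1e-4)
            assert err <= 5 * max(se[lv], 1e-4)   # hard cap
    assert total > 30
    # 3-SE exceedances occur at ~0.3% nominally; allow sampling noise
    assert bad / total <= 0.03


def test_lw_and_logic_sampling_identical_without_evidence(two_node_net):
    p1, _ = infer_lw(two_node_net, {}, "B", 5000, seed=7)
    p2 = infer_logic_sampling(two_node_net, {}, "B", 5000, seed=7)
    assert p1 == p2


def test_logic_sampling_matches_exact(two_node_net):
    exact = infer_exact(two_node_net, {"A": "1"}, "B")
    est = infer_logic_sampling(two_node_net, {"A": "1"}, "B", 200_000, seed=0)
    assert est["1"] == pytest.approx(exact["1"], abs=0.01)


def test_logic_sampling_impossible_evidence_reports_acceptance():
    lv = {"A": ("0", "1")}
    net = BayesNet(DAG(lv, {}), {"A": np.array([1.0, 0.0])})
    with pytest.raises(ImpossibleEvidenceError, match="acceptance rate"):
        infer_logic_sampling(net, {"A": "1"}, "A", 1000, seed=0)


def test_lw_lower_variance_than_logic_sampling(two_node_net):
    """Likelihood weighting beats rejection sampling on low-probability
    evidence at equal sample size."""
    lv = {"A": ("0", "1"), "B": ("0", "1")}
    net = BayesNet(DAG(lv, {"B": ("A",)}),
                   {"A": np.array([0.95, 0.05]),
                    "B": np.array([[0.9, 0.1], [0.2, 0.8]])})
    lw, ls = [], []
    for s in range(100):
        lw.append(infer_lw(net, {"A": "1"}, "B", 2000, seed=s)[0]["1"])
        ls.append(infer_logic_sampling(net, {"A": "1"}, "B", 2000, seed=s)["1"])
    assert np.var(lw) < np.var(ls)


def test_lw_error_shrinks_as_inverse_sqrt_n(two_node_net):
    net = two_node_net
    exact = infer_exact(net, {"B": "1"}, "A")["1"]
    sizes = [1_000, 10_000, 100_000]
    rmse = []
    for n in sizes:
        errs = [infer_lw(net, {"B": "1"}, "A", n, seed=s)[0]["1"] - exact
                for s in range(30)]
        rmse.append(np.sqrt(np.mean(np.square(errs))))
    slope = np.polyfit(np.log10(sizes), np.log10(rmse), 1)[0]
    assert -0.6 <= slope <= -0.4


def test_scenario_inference_monotone_and_batched(truth):
    worst = {"hb_low": "yes", "egfr_band": "<=59", "sodium_band": "hypo"}
    fixed = {"hb_low": "no", "egfr_band": ">=90", "sodium_band": "normal"}
    res = scenario_inference(truth, [worst, fixed, {}], query="aki",
                             n_samples=40_000, seed=0)
    assert res[0]["p_positive"] > res[1]["p_positive"]
    assert res[2]["delta_vs_marginal"]["yes"] == pytest.approx(0.0, abs=1e-12)


def test_truth_cpt_worst_configuration_has_maximal_risk(truth):
    cpt = truth.cpts["aki"][..., 1]
    worst = np.unravel_index(np.argmax(cpt), cpt.shape)
    # age <=29, anemia, eGFR <=59, hyponatremia, hyperkalemia
    assert worst == (0, 1, 2, 0, 2)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_json_round_trip(two_node_net, tmp_path):
    text = net_to_json(two_node_net)
    back = net_from_json(text)
    assert back.dag.arcs == two_node_net.dag.arcs
    for n in two_node_net.dag.nodes:
        assert np.allclose(back.cpts[n], two_node_net.cpts[n])


def test_bif_export_structure(two_node_net, tmp_path):
    path = tmp_path / "net.bif"
    write_bif(two_node_net, path)
    text = path.read_text()
    assert "variable A {" in text and "variable B {" in text
    assert "probability ( B | A )" in text
    assert text.count("probability") == 2
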
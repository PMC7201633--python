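"""Discrete Bayesian networks: structure scoring, tabu search, ML parameter
learning and probabilistic inference.

A network is a directed acyclic graph (DAG) over named categorical variables
plus one conditional probability table (CPT) per node.  The joint distribution
factorizes as ``P(X_1..X_n) = prod_i P(X_i | parents(X_i))``.

Structure learning maximizes the BIC score

    score(G) = sum_i [ LL_i - (d_i / 2) * ln N ]

where ``LL_i`` is the multinomial log-likelihood of node *i* given its parents
and ``d_i = (levels_i - 1) * prod(parent levels)``.  The score decomposes over
node families, so local search moves (add / delete / reverse arc) only rescore
the affected families.  Inference is available by exact enumeration (small
networks), likelihood weighting and forward ("logic") sampling with rejection.
"""

from __future__ import annotations

import itertools
import json
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DAG",
    "BayesNet",
    "TabuConfig",
    "bic_score",
    "tabu_learn",
    "fit_cpts",
    "infer_exact",
    "infer_lw",
    "infer_logic_sampling",
    "cpd_table",
    "scenario_inference",
    "sample_frame",
    "skeleton_hamming_distance",
    "net_to_json",
    "net_from_json",
    "write_bif",
]

# Exact enumeration refuses joint state spaces above this many configurations.
ENUMERATION_GUARD = 2 ** 20


class ImpossibleEvidenceError(ValueError):
    """Evidence has zero probability under the network."""


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over categorical variables.

    Parameters
    ----------
    levels
        Mapping node name -> ordered tuple of category labels.
    parents
        Mapping node name -> tuple of parent node names.  Nodes absent from
        the mapping have no parents.
    """

    levels: Mapping[str, tuple[str, ...]]
    parents: Mapping[str, tuple[str, ...]]

    def __post_init__(self):
        levels = {n: tuple(ls) for n, ls in self.levels.items()}
        parents = {n: tuple(self.parents.get(n, ())) for n in levels}
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "parents", parents)
        for child, ps in parents.items():
            for p in ps:
                if p not in levels:
                    raise ValueError(f"unknown parent {p!r} of {child!r}")
                if p == child:
                    raise ValueError(f"self-loop on {child!r}")
            if len(set(ps)) != len(ps):
                raise ValueError(f"duplicate parents of {child!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("graph contains a directed cycle")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.levels)

    @property
    def arcs(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (p, c) for c in self.nodes for p in self.parents[c]
        )

    def card(self, node: str) -> int:
        return len(self.levels[node])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for c, ps in self.parents.items():
            g.add_edges_from((p, c) for p in ps)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.to_networkx()))
        return order

    def with_parents(self, node: str, new_parents: Sequence[str]) -> "DAG":
        parents = dict(self.parents)
        parents[node] = tuple(new_parents)
        return DAG(self.levels, parents)


@dataclass
class BayesNet:
    """A DAG plus one CPT per node.

    CPTs are dense arrays with shape ``(*parent_cards, card)`` where the axes
    follow ``dag.parents[node]`` order and the trailing axis indexes the
    node's own levels.  Every row (trailing axis) sums to 1.
    """

    dag: DAG
    cpts: dict[str, np.ndarray]
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for {node!r}")
            cpt = np.asarray(self.cpts[node], dtype=float)
            shape = tuple(self.dag.card(p) for p in self.dag.parents[node])
            shape = shape + (self.dag.card(node),)
            if cpt.shape != shape:
                raise ValueError(
                    f"CPT for {node!r} has shape {cpt.shape}, expected {shape}"
                )
            rows = cpt.reshape(-1, cpt.shape[-1])
            if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {node!r} do not sum to 1")
            self.cpts[node] = cpt

    def level_index(self, node: str, level) -> int:
        try:
            return self.dag.levels[node].index(level)
        except ValueError:
            raise ValueError(f"{level!r} is not a level of {node!r}") from None


# ---------------------------------------------------------------------------
# data encoding and scoring
# ---------------------------------------------------------------------------

def encode_data(data: pd.DataFrame, levels: Mapping[str, Sequence[str]]) -> dict[str, np.ndarray]:
    """Integer-code columns of ``data`` according to ``levels``.

    Rows with values outside the level sets (including missing values) are
    dropped across all requested columns (complete-case analysis).
    """
    codes = {}
    mask = np.ones(len(data), dtype=bool)
    for node, lvls in levels.items():
        if node not in data.columns:
            raise ValueError(f"node {node!r} absent from data")
        cat = pd.Categorical(data[node], categories=list(lvls))
        c = np.asarray(cat.codes)
        mask &= c >= 0
        codes[node] = c
    return {n: c[mask] for n, c in codes.items()}


def _family_counts(
    child: np.ndarray, card: int, parent_codes: Sequence[np.ndarray], parent_cards: Sequence[int]
) -> np.ndarray:
    """Contingency counts of a node family, shape (n_parent_configs, card)."""
    if parent_cards:
        idx = np.ravel_multi_index([np.asarray(p) for p in parent_codes], tuple(parent_cards))
        nconf = int(np.prod(parent_cards))
    else:
        idx = np.zeros(len(child), dtype=np.intp)
        nconf = 1
    flat = idx * card + child
    return np.bincount(flat, minlength=nconf * card).reshape(nconf, card)


def _family_score(counts: np.ndarray, n_total: int, card: int) -> float:
    """BIC contribution of one family: multinomial LL minus (d/2) ln N."""
    rowsum = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(counts > 0, counts * np.log(counts / rowsum), 0.0).sum()
    d = (card - 1) * counts.shape[0]
    return float(ll - 0.5 * d * np.log(n_total))


class _Scorer:
    """Caches per-family BIC scores over integer-coded data."""

    def __init__(self, codes: Mapping[str, np.ndarray], cards: Mapping[str, int]):
        self.codes = codes
        self.cards = cards
        self.n = len(next(iter(codes.values()))) if codes else 0
        self._cache: dict[tuple, float] = {}

    def family(self, child: str, parents: tuple[str, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            counts = _family_counts(
                self.codes[child],
                self.cards[child],
                [self.codes[p] for p in parents],
                [self.cards[p] for p in parents],
            )
            self._cache[key] = _family_score(counts, self.n, self.cards[child])
        return self._cache[key]


def bic_score(dag: DAG, data: pd.DataFrame) -> tuple[float, dict[str, float]]:
    """BIC network score and its per-node decomposition on complete cases."""
    codes = encode_data(data, dag.levels)
    n = len(next(iter(codes.values())))
    if n == 0:
        raise ValueError("no complete cases")
    scorer = _Scorer(codes, {m: dag.card(m) for m in dag.nodes})
    per_node = {m: scorer.family(m, dag.parents[m]) for m in dag.nodes}
    return sum(per_node.values()), per_node


# ---------------------------------------------------------------------------
# tabu structure search
# ---------------------------------------------------------------------------

@dataclass
class TabuConfig:
    tabu_len: int = 10
    max_iter: int = 10_000
    patience: int = 15  # stop after this many moves without improving the best
    restarts: int = 0
    seed: int = 0
    max_parents: int | None = None
    whitelist: tuple[tuple[str, str], ...] = ()
    blacklist: tuple[tuple[str, str], ...] = ()


def _reachable(parents: Mapping[str, tuple[str, ...]], src: str, dst: str) -> bool:
    children: dict[str, list[str]] = {n: [] for n in parents}
    for c, ps in parents.items():
        for p in ps:
            children[p].append(c)
    stack, seen = [src], set()
    while stack:
        x = stack.pop()
        if x == dst:
            return True
        if x in seen:
            continue
        seen.add(x)
        stack.extend(children[x])
    return False


def tabu_learn(
    data: pd.DataFrame,
    levels: Mapping[str, Sequence[str]],
    config: TabuConfig | None = None,
) -> DAG:
    """Learn a DAG by BIC-maximizing tabu search over arc moves.

    Moves are arc additions, deletions and reversals.  The search may accept
    the best non-tabu move even when it worsens the score (that is what lets
    it escape local optima); the best structure ever visited is returned.
    Ties between equal-score moves break lexicographically, so the result is
    deterministic for a given seed.
    """
    cfg = config or TabuConfig()
    levels = {n: tuple(ls) for n, ls in levels.items()}
    if len(levels) < 2:
        raise ValueError("need at least 2 variables")
    codes = encode_data(data, levels)
    cards = {n: len(ls) for n, ls in levels.items()}
    scorer = _Scorer(codes, cards)
    blacklist = set(map(tuple, cfg.blacklist))
    whitelist = [tuple(a) for a in cfg.whitelist]

    start = {n: () for n in levels}
    for u, v in whitelist:
        if (u, v) in blacklist:
            raise ValueError(f"arc {u}->{v} both whitelisted and blacklisted")
        if _reachable(start, v, u):
            raise ValueError(f"whitelist arc {u}->{v} induces a cycle")
        start[v] = start[v] + (u,)

    rng = np.random.default_rng(cfg.seed)
    best_parents, best_score = None, -np.inf
    for restart in range(cfg.restarts + 1):
        parents = {n: tuple(ps) for n, ps in start.items()}
        if restart > 0:
            parents = _random_start(levels, whitelist, blacklist, cfg, rng)
        p, s = _tabu_run(parents, levels, scorer, whitelist, blacklist, cfg)
        if s > best_score + 1e-12:
            best_parents, best_score = p, s
    return DAG(levels, best_parents)


def _random_start(levels, whitelist, blacklist, cfg, rng):
    nodes = list(levels)
    parents = {n: () for n in nodes}
    for u, v in whitelist:
        parents[v] = parents[v] + (u,)
    pairs = [(u, v) for u in nodes for v in nodes if u != v and (u, v) not in blacklist]
    rng.shuffle(pairs)
    for u, v in pairs[: len(nodes)]:
        if u in parents[v] or _reachable(parents, v, u):
            continue
        if cfg.max_parents and len(parents[v]) >= cfg.max_parents:
            continue
        parents[v] = parents[v] + (u,)
    return parents


def _tabu_run(parents, levels, scorer, whitelist, blacklist, cfg):
    nodes = list(levels)
    forced = set(whitelist)
    score = sum(scorer.family(n, parents[n]) for n in nodes)
    best_parents = {n: ps for n, ps in parents.items()}
    best_score = score
    tabu: deque[tuple] = deque(maxlen=max(cfg.tabu_len, 1))
    stall = 0
    for _ in range(cfg.max_iter):
        candidates = []
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                has = u in parents[v]
                if not has:
                    if (u, v) in blacklist:
                        continue
                    if cfg.max_parents is not None and len(parents[v]) >= cfg.max_parents:
                        continue
                    if _reachable(parents, v, u):
                        continue
                    delta = scorer.family(v, parents[v] + (u,)) - scorer.family(v, parents[v])
                    candidates.append((delta, "add", u, v))
                else:
                    if (u, v) not in forced:
                        new = tuple(p for p in parents[v] if p != u)
                        delta = scorer.family(v, new) - scorer.family(v, parents[v])
                        candidates.append((delta, "del", u, v))
                    # reversal u->v becomes v->u
                    if (u, v) not in forced and (v, u) not in blacklist:
                        if not (cfg.max_parents is not None and len(parents[u]) >= cfg.max_parents):
                            without = tuple(p for p in parents[v] if p != u)
                            if not _reachable({**parents, v: without}, u, v):
                                delta = (
                                    scorer.family(v, without)
                                    - scorer.family(v, parents[v])
                                    + scorer.family(u, parents[u] + (v,))
                                    - scorer.family(u, parents[u])
                                )
                                candidates.append((delta, "rev", u, v))
        if not candidates:
            break
        # deterministic: best delta, ties by lexicographic move key
        candidates.sort(key=lambda m: (-m[0], m[1], m[2], m[3]))
        chosen = None
        for delta, kind, u, v in candidates:
            key = (kind, u, v)
            aspiration = score + delta > best_score + 1e-12
            if key in tabu and not aspiration:
                continue
            chosen = (delta, kind, u, v)
            break
        if chosen is None:
            break
        delta, kind, u, v = chosen
        if kind == "add":
            parents[v] = parents[v] + (u,)
            tabu.append(("del", u, v))
        elif kind == "del":
            parents[v] = tuple(p for p in parents[v] if p != u)
            tabu.append(("add", u, v))
        else:
            parents[v] = tuple(p for p in parents[v] if p != u)
            parents[u] = parents[u] + (v,)
            tabu.append(("rev", v, u))
        score += delta
        if score > best_score + 1e-12:
            best_score = score
            best_parents = {n: ps for n, ps in parents.items()}
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return best_parents, best_score


# ---------------------------------------------------------------------------
# parameter learning
# ---------------------------------------------------------------------------

def fit_cpts(dag: DAG, data: pd.DataFrame, smoothing: float = 0.0) -> BayesNet:
    """Maximum-likelihood CPTs (relative frequencies, optional pseudo-count).

    Parent configurations never observed in the data fall back to a uniform
    row with a warning; this keeps downstream inference free of structurally
    impossible (zero-probability) evidence.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    codes = encode_data(data, dag.levels)
    cpts, counts = {}, {}
    for node in dag.nodes:
        ps = dag.parents[node]
        card = dag.card(node)
        cnt = _family_counts(
            codes[node], card, [codes[p] for p in ps], [dag.card(p) for p in ps]
        ).astype(float)
        counts[node] = cnt.copy()
        cnt += smoothing
        rowsum = cnt.sum(axis=1, keepdims=True)
        empty = rowsum[:, 0] == 0
        if empty.any():
            warnings.warn(
                f"{int(empty.sum())} unobserved parent configuration(s) for "
                f"{node!r}; using uniform rows",
                stacklevel=2,
            )
            cnt[empty] = 1.0
            rowsum = cnt.sum(axis=1, keepdims=True)
        probs = cnt / rowsum
        shape = tuple(dag.card(p) for p in ps) + (card,)
        cpts[node] = probs.reshape(shape)
        counts[node] = counts[node].reshape(shape)
    return BayesNet(dag, cpts, counts)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _evidence_indices(net: BayesNet, evidence: Mapping[str, object]) -> dict[str, int]:
    return {n: net.level_index(n, v) for n, v in evidence.items()}


def infer_exact(
    net: BayesNet, evidence: Mapping[str, object], query: str
) -> dict[str, float]:
    """Posterior of ``query`` by exact enumeration over unobserved nodes.

    The factorized joint is instantiated only over the unobserved variables
    (evidence axes are sliced out), multiplied by broadcasting and summed out,
    so the cost is the product of the unobserved cardinalities.
    """
    if query not in net.dag.nodes:
        raise ValueError(f"unknown query node {query!r}")
    ev = _evidence_indices(net, evidence)
    if query in ev:
        out = {lv: 0.0 for lv in net.dag.levels[query]}
        out[net.dag.levels[query][ev[query]]] = 1.0
        return out
    # barren-node pruning: variables that are not ancestors of the query or
    # of any evidence node integrate out to 1 and can be dropped
    g = net.dag.to_networkx()
    keep = {query, *ev}
    for n in list(keep):
        keep |= nx.ancestors(g, n)
    relevant = [n for n in net.dag.nodes if n in keep]
    free = [n for n in relevant if n not in ev]
    size = int(np.prod([net.dag.card(n) for n in free]))
    if size > ENUMERATION_GUARD:
        raise ValueError(
            f"state space of {size} unobserved configurations exceeds the "
            f"enumeration guard ({ENUMERATION_GUARD}); use infer_lw"
        )
    axis_of = {n: i for i, n in enumerate(free)}
    joint = np.ones([net.dag.card(n) for n in free])
    for node in relevant:
        cpt = net.cpts[node]
        involved = list(net.dag.parents[node]) + [node]
        # slice evidence-fixed axes, broadcast the rest into joint's axes
        index: list[object] = []
        out_axes = []
        for v in involved:
            if v in ev:
                index.append(ev[v])
            else:
                index.append(slice(None))
                out_axes.append(axis_of[v])
        factor = np.asarray(cpt[tuple(index)])
        if out_axes:
            # transpose surviving axes into joint-axis order, then expand
            factor = np.transpose(factor, axes=np.argsort(out_axes))
            shape = [1] * len(free)
            for ax in sorted(out_axes):
                shape[ax] = net.dag.card(free[ax])
            factor = factor.reshape(shape)
        joint = joint * factor
    sum_axes = tuple(i for n, i in axis_of.items() if n != query)
    marg = joint.sum(axis=sum_axes) if sum_axes else joint
    total = float(marg.sum())
    if total <= 0:
        raise ImpossibleEvidenceError("impossible evidence")
    marg = marg / total
    return {lv: float(p) for lv, p in zip(net.dag.levels[query], marg)}


def _sample_topological(
    net: BayesNet,
    n_samples: int,
    rng: np.random.Generator,
    evidence_idx: Mapping[str, int],
    weighted: bool,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Ancestral sampling; evidence nodes are clamped (weighted=True) or
    sampled like any other node (weighted=False)."""
    samples: dict[str, np.ndarray] = {}
    logw = np.zeros(n_samples)
    for node in net.dag.topological_order():
        cpt = net.cpts[node]
        ps = net.dag.parents[node]
        if ps:
            rows = cpt[tuple(samples[p] for p in ps)]
        else:
            rows = np.broadcast_to(cpt, (n_samples, cpt.shape[-1]))
        if weighted and node in evidence_idx:
            idx = evidence_idx[node]
            samples[node] = np.full(n_samples, idx, dtype=np.intp)
            with np.errstate(divide="ignore"):
                logw += np.log(rows[:, idx])
        else:
            u = rng.random(n_samples)
            cum = np.cumsum(rows, axis=1)
            samples[node] = (u[:, None] > cum[:, :-1]).sum(axis=1).astype(np.intp)
    return samples, logw


def infer_lw(
    net: BayesNet,
    evidence: Mapping[str, object],
    query: str,
    n_samples: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Likelihood-weighting posterior of ``query`` plus Monte-Carlo SEs.

    Evidence nodes are clamped to their observed levels; each sample is
    weighted by the product of the evidence likelihoods given the sampled
    parents.  Returns ``(probabilities, standard_errors)`` keyed by level.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ev = _evidence_indices(net, evidence)
    rng = np.random.default_rng(seed)
    samples, logw = _sample_topological(net, n_samples, rng, ev, weighted=True)
    w = np.exp(logw)
    wsum = w.sum()
    if wsum <= 0:
        raise ImpossibleEvidenceError("evidence unreachable: all weights zero")
    q = samples[query]
    probs, ses = {}, {}
    for i, lv in enumerate(net.dag.levels[query]):
        ind = (q == i).astype(float)
        mu = float(np.sum(w * ind) / wsum)
        # ratio-estimator (self-normalized importance sampling) variance
        var = float(np.sum((w / wsum) ** 2 * (ind - mu) ** 2))
        probs[lv] = mu
        ses[lv] = np.sqrt(var)
    return probs, ses


def infer_logic_sampling(
    net: BayesNet,
    evidence: Mapping[str, object],
    query: str,
    n_samples: int = 10_000,
    seed: int = 0,
) -> dict[str, float]:
    """Forward sampling with rejection of evidence-inconsistent samples."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ev = _evidence_indices(net, evidence)
    rng = np.random.default_rng(seed)
    samples, _ = _sample_topological(net, n_samples, rng, ev, weighted=False)
    accept = np.ones(n_samples, dtype=bool)
    for node, idx in ev.items():
        accept &= samples[node] == idx
    n_acc = int(accept.sum())
    if n_acc == 0:
        raise ImpossibleEvidenceError(
            f"zero accepted samples (acceptance rate 0/{n_samples})"
        )
    q = samples[query][accept]
    return {
        lv: float(np.mean(q == i)) for i, lv in enumerate(net.dag.levels[query])
    }


def cpd_table(net: BayesNet, node: str, percent: bool = True) -> pd.DataFrame:
    """CPT of ``node`` as a tidy table, one row per parent configuration.

    Rows iterate parent levels in CPT (row-major) order; probabilities are
    expressed as percentages by default so each printed row pair sums to 100.
    """
    ps = net.dag.parents[node]
    cpt = net.cpts[node].reshape(-1, net.dag.card(node))
    configs = list(itertools.product(*[net.dag.levels[p] for p in ps])) or [()]
    rows = []
    scale = 100.0 if percent else 1.0
    for cfg, row in zip(configs, cpt):
        rec = {p: lv for p, lv in zip(ps, cfg)}
        for lv, pr in zip(net.dag.levels[node], row):
            rec[f"P({node}={lv})" + ("%" if percent else "")] = pr * scale
        rows.append(rec)
    return pd.DataFrame(rows)


def scenario_inference(
    net: BayesNet,
    evidence_sets: Sequence[Mapping[str, object]],
    query: str = "aki",
    n_samples: int = 100_000,
    seed: int = 0,
    positive_level: str | None = None,
) -> list[dict]:
    """Posterior P(query | evidence) for a batch of evidence scenarios.

    All scenarios share the same seed (so differences are attributable to the
    evidence, not the Monte-Carlo stream) and each result reports the delta
    against the no-evidence marginal.
    """
    marginal, _ = infer_lw(net, {}, query, n_samples=n_samples, seed=seed)
    pos = positive_level or net.dag.levels[query][-1]
    out = []
    for ev in evidence_sets:
        post, se = infer_lw(net, ev, query, n_samples=n_samples, seed=seed)
        out.append(
            {
                "evidence": dict(ev),
                "posterior": post,
                "se": se,
                "delta_vs_marginal": {
                    lv: post[lv] - marginal[lv] for lv in post
                },
                "p_positive": post[pos],
            }
        )
    return out


# ---------------------------------------------------------------------------
# sampling data frames and utilities
# ---------------------------------------------------------------------------

def sample_frame(net: BayesNet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Forward-sample ``n`` complete records from the network as a DataFrame
    of category labels (column order follows ``net.dag.nodes``)."""
    if n == 0:
        return pd.DataFrame({node: pd.Series(dtype=object) for node in net.dag.nodes})
    samples, _ = _sample_topological(net, n, rng, {}, weighted=False)
    data = {}
    for node in net.dag.nodes:
        lv = np.asarray(net.dag.levels[node], dtype=object)
        data[node] = lv[samples[node]]
    return pd.DataFrame(data)


def skeleton_hamming_distance(a: DAG | Iterable[tuple[str, str]], b: DAG | Iterable[tuple[str, str]]) -> int:
    """Number of undirected edges present in exactly one of two graphs."""
    def edges(x):
        arcs = x.arcs if isinstance(x, DAG) else x
        return {frozenset(e) for e in arcs}
    return len(edges(a) ^ edges(b))


# ---------------------------------------------------------------------------
# serialization: canonical JSON and BIF export
# ---------------------------------------------------------------------------

def net_to_json(net: BayesNet) -> str:
    payload = {
        "nodes": [
            {
                "name": n,
                "levels": list(net.dag.levels[n]),
                "parents": list(net.dag.parents[n]),
                "cpt": np.asarray(net.cpts[n]).reshape(-1, net.dag.card(n)).tolist(),
            }
            for n in net.dag.nodes
        ]
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def net_from_json(text: str) -> BayesNet:
    payload = json.loads(text)
    levels = {d["name"]: tuple(d["levels"]) for d in payload["nodes"]}
    parents = {d["name"]: tuple(d["parents"]) for d in payload["nodes"]}
    dag = DAG(levels, parents)
    cpts = {}
    for d in payload["nodes"]:
        n = d["name"]
        shape = tuple(dag.card(p) for p in dag.parents[n]) + (dag.card(n),)
        cpts[n] = np.asarray(d["cpt"], dtype=float).reshape(shape)
    return BayesNet(dag, cpts)


def write_bif(net: BayesNet, path, name: str = "akinet") -> None:
    """Export to the Bayesian Interchange Format used by standard BN tools."""
    def clean(s):
        return str(s).replace(" ", "_").replace(",", "_")

    lines = [f"network {clean(name)} {{", "}"]
    for n in net.dag.nodes:
        lvls = ", ".join(clean(l) for l in net.dag.levels[n])
        lines += [
            f"variable {clean(n)} {{",
            f"  type discrete [ {net.dag.card(n)} ] {{ {lvls} }};",
            "}",
        ]
    for n in net.dag.nodes:
        ps = net.dag.parents[n]
        cpt = net.cpts[n].reshape(-1, net.dag.card(n))
        if not ps:
            head = f"probability ( {clean(n)} ) {{"
            body = ["  table " + ", ".join(f"{p:.10g}" for p in cpt[0]) + ";"]
        else:
            head = f"probability ( {clean(n)} | {', '.join(clean(p) for p in ps)} ) {{"
            body = []
            for cfg, row in zip(
                itertools.product(*[net.dag.levels[p] for p in ps]), cpt
            ):
                key = ", ".join(clean(c) for c in cfg)
                body.append(
                    f"  ({key}) " + ", ".join(f"{p:.10g}" for p in row) + ";"
                )
        lines += [head, *body, "}"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
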
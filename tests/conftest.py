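import numpy as np
import pytest

from akinet.synthetic import (CohortParams, simulate_coded, simulate_cohort,
                              table1_fixture, truth_net)


@pytest.fixture(scope="session")
def fixture_tables():
    return table1_fixture()


@pytest.fixture(scope="session")
def truth():
    return truth_net()


@pytest.fixture(scope="session")
def coded_2000():
    return simulate_coded(CohortParams(n_patients=2000, seed=17))


@pytest.fixture(scope="session")
def records_600():
    return simulate_cohort(CohortParams(n_patients=600, seed=5))


def make_random_net(rng, n_nodes=5, max_levels=3):
    """Random small discrete BN with dense (bounded-away-from-zero) CPTs."""
    from akinet.bn import DAG, BayesNet

    names = [f"X{i}" for i in range(n_nodes)]
    levels = {n: ("a", "b", "c")[: rng.integers(2, max_levels + 1)] for n in names}
    parents = {}
    for i, n in enumerate(names):
        pool = names[:i]
        k = rng.integers(0, min(2, len(pool)) + 1)
        parents[n] = tuple(rng.choice(pool, size=k, replace=False)) if k else ()
    dag = DAG(levels, parents)
    cpts = {}
    for n in names:
        shape = tuple(len(levels[p]) for p in parents[n]) + (len(levels[n]),)
        raw = rng.gamma(1.0, 1.0, size=shape) + 0.05
        cpts[n] = raw / raw.sum(-1, keepdims=True)
    return BayesNet(dag, cpts)
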
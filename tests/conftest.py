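import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import settings

import adlsim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def minimal_bundle():
    return adlsim.make_fixture("minimal")


@pytest.fixture(scope="session")
def paper_bundle():
    return adlsim.make_fixture("paper-like")


@pytest.fixture(scope="session")
def paper_pair(paper_bundle):
    """Parsed (script, context) of the paper-like fixture."""
    script = adlsim.parse_adl_script(paper_bundle.adl_script)
    ctx = adlsim.parse_context(paper_bundle.context_json)
    return script, ctx


@pytest.fixture(scope="session")
def paper_sim_101(paper_pair):
    script, ctx = paper_pair
    return adlsim.run_simulation(script, ctx, adlsim.SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def paper_sim_202(paper_pair):
    script, ctx = paper_pair
    return adlsim.run_simulation(script, ctx, adlsim.SimulationConfig(seed=202))


def fisher_oracle(table: np.ndarray) -> float:
    """Brute-force two-sided Fisher p for a 2xK table.

    Independent of the package: enumerates every first row compatible with
    the margins via itertools.product and sums multivariate-hypergeometric
    probabilities (exact integer combinatorics, normalised at the end) of
    all tables no more probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    col_sums = table.sum(axis=0)
    row0 = int(table[0].sum())
    weights = {}
    for first_row in itertools.product(*[range(c + 1) for c in col_sums]):
        if sum(first_row) != row0:
            continue
        w = 1
        for a, c in zip(first_row, col_sums):
            w *= comb(int(c), a)
        weights[first_row] = w
    total = sum(weights.values())
    w_obs = weights[tuple(int(x) for x in table[0])]
    hit = sum(w for w in weights.values() if w <= w_obs * (1 + 1e-7))
    return hit / total
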
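"""Shared fixtures.

Expensive Monte-Carlo artifacts (replicate fits, the reference-scenario
posterior) are session-scoped so property tests and acceptance tests share
one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rankggm.cohort import CohortTable, VariableSchema
from rankggm.copula import gibbs_sample, select_edges
from rankggm.simulate import default_scenario, generate_wave1


def make_gaussian_table(X: np.ndarray, names: list[str] | None = None) -> CohortTable:
    """Wrap a numeric matrix as an all-continuous single-stratum cohort."""
    n, p = X.shape
    names = names or [f"v{j}" for j in range(p)]
    schema = [VariableSchema(nm, "continuous") for nm in names]
    ids = [f"s{i:05d}" for i in range(n)]
    values = pd.DataFrame(np.asarray(X, dtype=float), index=ids, columns=names)
    sex = pd.Series(["female"] * n, index=ids)
    age = pd.Series(75.0, index=ids)
    return CohortTable(ids, values, sex, age, 1, schema)


def random_correlation(p: int, rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((p, p))
    S = A @ A.T + p * np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


@pytest.fixture(scope="session")
def fixture_config():
    """The shipped 11-node reference scenario (n=450 per sex)."""
    return default_scenario()


@pytest.fixture(scope="session")
def fixture_wave1(fixture_config):
    return generate_wave1(fixture_config)


@pytest.fixture(scope="session")
def fixture_fits(fixture_wave1):
    """Full-length posterior fits of both sex strata on the reference scenario."""
    from rankggm.cohort import split_by_sex

    female, male = split_by_sex(fixture_wave1)
    return {
        "female": gibbs_sample(female, n_draws=5000, burn_in=500, seed=42),
        "male": gibbs_sample(male, n_draws=5000, burn_in=500, seed=43),
    }


@pytest.fixture(scope="session")
def null_single_fits():
    """200 replicate fits of independent Gaussian data (p=6, n=300, 1000 draws).

    Returns the per-replicate adjacency matrices from 95% CI selection.
    """
    adjacencies = []
    for rep in range(200):
        rng = np.random.default_rng(5000 + rep)
        X = rng.standard_normal((300, 6))
        sample = gibbs_sample(
            make_gaussian_table(X), n_draws=1000, burn_in=300, seed=9000 + rep
        )
        adjacencies.append(select_edges(sample).adjacency)
    return adjacencies


@pytest.fixture(scope="session")
def null_two_group_fits():
    """200 replicate pairs of fits from ONE generating network (p=6, n=300).

    Both groups share the same sparse partial-correlation structure, so any
    significant between-group difference is a false positive.  Returns a list
    of (sample_a, sample_b) posterior pairs.
    """
    from rankggm.simulate import correlation_from_partials

    P = np.zeros((6, 6))
    P[0, 1] = P[1, 0] = 0.30
    P[2, 3] = P[3, 2] = -0.25
    R = correlation_from_partials(P)
    L = np.linalg.cholesky(R)
    pairs = []
    for rep in range(200):
        rng = np.random.default_rng(20_000 + rep)
        Xa = rng.standard_normal((300, 6)) @ L.T
        Xb = rng.standard_normal((300, 6)) @ L.T
        sa = gibbs_sample(make_gaussian_table(Xa), n_draws=1000, burn_in=300, seed=30_000 + rep)
        sb = gibbs_sample(make_gaussian_table(Xb), n_draws=1000, burn_in=300, seed=40_000 + rep)
        pairs.append((sa, sb))
    return pairs
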
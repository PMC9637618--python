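"""Numba-compiled Gibbs sweep for the rank-likelihood copula sampler.

The latent matrix Z is updated one column (variable) at a time.  Within a
column, observed cells are visited level-by-level (ascending observed value,
then subject order).  Under the maintained consistency invariant — every
latent at a lower level is below every latent at a higher level — the
single-cell full-conditional truncation window is exactly

    ( max latent of the adjacent lower level , min latent of the adjacent
      upper level )

so the sweep is O(n) per column while remaining a valid single-site Gibbs
scan.  Missing cells are drawn from the untruncated conditional, which is
the in-sampler posterior-predictive imputation.  The precision matrix K is
then redrawn from its conjugate Wishart full conditional.
"""

import math

import numpy as np
from numba import njit

_SQRT2PI = 2.5066282746310002


@njit(cache=False)
def _phi(x):
    """Standard normal CDF via erfc (accurate in both tails)."""
    return 0.5 * math.erfc(-x * 0.7071067811865475)


@njit(cache=False)
def _ndtri(u):
    """Inverse standard normal CDF (Acklam's rational approx + one Halley step)."""
    if u <= 0.0:
        return -np.inf
    if u >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    plow = 0.02425
    if u < plow:
        q = math.sqrt(-2.0 * math.log(u))
        x = (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    elif u <= 1.0 - plow:
        q = u - 0.5
        r = q * q
        x = (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
            (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - u))
        x = -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
            ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    # Halley refinement
    e = _phi(x) - u
    g = e * _SQRT2PI * math.exp(0.5 * x * x)
    x = x - g / (1.0 + 0.5 * x * g)
    return x


@njit(cache=False)
def _tnorm_std(alpha, beta):
    """Draw from a standard normal truncated to (alpha, beta) by inverse CDF."""
    pa = 0.0 if alpha == -np.inf else _phi(alpha)
    pb = 1.0 if beta == np.inf else _phi(beta)
    width = pb - pa
    if width < 1e-15:
        # window numerically empty (deep-tail adjacent order statistics):
        # fall back to the midpoint / nearest finite bound
        if alpha == -np.inf:
            return beta
        if beta == np.inf:
            return alpha
        return 0.5 * (alpha + beta)
    u = pa + np.random.random() * width
    if u < 1e-300:
        u = 1e-300
    if u > 1.0 - 1e-16:
        u = 1.0 - 1e-16
    x = _ndtri(u)
    if x < alpha:
        x = alpha
    elif x > beta:
        x = beta
    return x


@njit(cache=False)
def _wishart(df, L_scale_inv):
    """Draw K ~ Wishart(df, V) where V = (L L^T)^{-1} and L = chol(S).

    Uses the Bartlett construction: K = M A A^T M^T with M M^T = V, taking
    M = L^{-T} (solved, not inverted explicitly).
    """
    p = L_scale_inv.shape[0]
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = math.sqrt(np.random.gamma(0.5 * (df - i), 2.0))
        for j in range(i):
            A[i, j] = np.random.standard_normal()
    M = np.linalg.solve(L_scale_inv.T, A)  # L^T M = A  ->  M = L^{-T} A
    return M @ M.T


@njit(cache=False)
def run_chain(
    Z0,            # float64[n, p] initial latents, consistent with bounds
    obs_order,     # int64[total_obs] subjects, per column sorted by (level, subject)
    col_ptr,       # int64[p+1] column offsets into obs_order / level structure
    lvl_ptr,       # int64[] per-column level boundaries (offsets into obs_order)
    lvl_col_ptr,   # int64[p+1] offsets into lvl_ptr (column j owns lvl_col_ptr[j]..lvl_col_ptr[j+1], inclusive fence)
    miss_order,    # int64[total_miss] missing subjects per column, subject order
    miss_ptr,      # int64[p+1]
    n_iter,        # total sweeps = burn_in + n_draws * thin
    burn_in,
    thin,
    prior_df,
    seed,
):
    """Run the Gibbs chain; returns retained precision-matrix draws."""
    np.random.seed(seed)
    Z = Z0.copy()
    n, p = Z.shape
    K = np.eye(p)
    n_keep = (n_iter - burn_in) // thin
    out = np.zeros((n_keep, p, p))
    kept = 0
    df = prior_df + n
    for it in range(n_iter):
        for j in range(p):
            kjj = K[j, j]
            sd = 1.0 / math.sqrt(kjj)
            # conditional means from the other columns only
            m = np.zeros(n)
            for k in range(p):
                if k != j:
                    ck = K[k, j]
                    if ck != 0.0:
                        for i in range(n):
                            m[i] += ck * Z[i, k]
            for i in range(n):
                m[i] = -m[i] / kjj

            lo_lvl = lvl_col_ptr[j]
            hi_lvl = lvl_col_ptr[j + 1]
            n_levels = hi_lvl - lo_lvl
            # current per-level minimum (pre-sweep values of untouched levels)
            lvl_min = np.empty(n_levels)
            for g in range(n_levels):
                s = lvl_ptr[lo_lvl + g]
                e = lvl_ptr[lo_lvl + g + 1]
                mn = np.inf
                for t in range(s, e):
                    v = Z[obs_order[t], j]
                    if v < mn:
                        mn = v
                lvl_min[g] = mn
            lower = -np.inf
            for g in range(n_levels):
                upper = lvl_min[g + 1] if g + 1 < n_levels else np.inf
                newmax = -np.inf
                s = lvl_ptr[lo_lvl + g]
                e = lvl_ptr[lo_lvl + g + 1]
                for t in range(s, e):
                    i = obs_order[t]
                    a = (lower - m[i]) / sd
                    b = (upper - m[i]) / sd
                    z = m[i] + sd * _tnorm_std(a, b)
                    Z[i, j] = z
                    if z > newmax:
                        newmax = z
                lower = newmax
            for t in range(miss_ptr[j], miss_ptr[j + 1]):
                i = miss_order[t]
                Z[i, j] = m[i] + sd * np.random.standard_normal()

        # standardize latent columns (scale is not identified by ranks)
        for j in range(p):
            mu = 0.0
            for i in range(n):
                mu += Z[i, j]
            mu /= n
            ss = 0.0
            for i in range(n):
                d = Z[i, j] - mu
                ss += d * d
            s = math.sqrt(ss / (n - 1))
            if s > 0.0:
                for i in range(n):
                    Z[i, j] = (Z[i, j] - mu) / s

        # conjugate Wishart update of the precision matrix
        S = np.eye(p) + Z.T @ Z
        L = np.linalg.cholesky(S)
        K = _wishart(df, L)

        if it >= burn_in and (it - burn_in) % thin == 0:
            out[kept] = K
            kept += 1
    return out
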
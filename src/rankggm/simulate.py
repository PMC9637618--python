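"""Two-wave synthetic cohorts with a known latent partial-correlation network.

Each sex stratum gets its own ground-truth partial-correlation matrix.  Rows
are drawn as latent multivariate Gaussians with the implied correlation
matrix and pushed through per-variable monotone margin maps (probability
integral transform), so ranks — and hence everything the copula estimator
sees — are inherited from the latent layer.  Zero inflation is implemented
as left-censoring of the latent variable at the inflation quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    SEX_LABELS,
    CohortTable,
    VariableSchema,
    default_schema,
    network_nodes,
)
from .errors import ConfigurationError, DegenerateSimulationError

__all__ = [
    "MarginSpec",
    "GeneratorConfig",
    "correlation_from_partials",
    "generate_wave1",
    "simulate_attrition",
    "true_network",
    "default_scenario",
]

MARGIN_KINDS = (
    "zero_inflated_lognormal",
    "count_binomialish",
    "gaussian",
    "ordinal_cutpoints",
    "bernoulli",
)

#: variables re-drawn at wave 2; the rest are frozen traits
TIME_VARYING = ("IL6", "IL8", "IL10", "IL12", "CRP", "depression", "cognition")


@dataclass(frozen=True)
class MarginSpec:
    """Monotone map from a latent standard normal to an observed margin."""

    kind: str
    p_zero: float = 0.0          # zero_inflated_lognormal
    log_mu: float = 0.0
    log_sigma: float = 1.0
    n_trials: int = 15           # count_binomialish
    p_success: float = 0.15
    mu: float = 0.0              # gaussian
    sigma: float = 1.0
    cutpoints: tuple[float, ...] = ()  # ordinal_cutpoints, on the latent z scale
    range_min: int = 1
    p: float = 0.5               # bernoulli

    def __post_init__(self) -> None:
        if self.kind not in MARGIN_KINDS:
            raise ConfigurationError(f"unknown margin kind {self.kind!r}")
        if not 0.0 <= self.p_zero < 1.0:
            raise ConfigurationError(f"p_zero must be in [0, 1): {self.p_zero}")
        if self.kind == "ordinal_cutpoints":
            cps = np.asarray(self.cutpoints, dtype=float)
            if cps.size == 0 or np.any(np.diff(cps) <= 0):
                raise ConfigurationError("cutpoints must be non-empty and strictly increasing")
        if self.kind == "bernoulli" and not 0.0 < self.p < 1.0:
            raise ConfigurationError(f"bernoulli p must be in (0, 1): {self.p}")

    def transform(self, z: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """Apply the margin to latent standard-normal draws.

        ``shift`` moves the latent mean before the transform (used for
        wave-2 mean shifts); monotonicity is preserved for any shift.
        """
        z = np.asarray(z, dtype=float) + shift
        if self.kind == "gaussian":
            return self.mu + self.sigma * z
        if self.kind == "ordinal_cutpoints":
            return self.range_min + np.searchsorted(np.asarray(self.cutpoints), z)
        if self.kind == "bernoulli":
            return (z > stats.norm.ppf(1.0 - self.p)).astype(float)
        u = stats.norm.cdf(z)
        if self.kind == "count_binomialish":
            return stats.binom.ppf(u, self.n_trials, self.p_success)
        # zero_inflated_lognormal: latent below the inflation quantile -> exact 0
        out = np.zeros_like(u)
        pos = u >= self.p_zero
        if self.p_zero < 1.0:
            u_rescaled = (u[pos] - self.p_zero) / (1.0 - self.p_zero)
            u_rescaled = np.clip(u_rescaled, 1e-12, 1.0 - 1e-12)
            out[pos] = np.exp(self.log_mu + self.log_sigma * stats.norm.ppf(u_rescaled))
        return out


def correlation_from_partials(partials: np.ndarray) -> np.ndarray:
    """Correlation matrix whose partial correlations equal ``partials``.

    Builds the unit-diagonal precision-like matrix with off-diagonal
    -partials, inverts it, and standardizes to a correlation.  The inverse of
    :func:`rankggm.copula.partials_from_precision` up to variable scale.
    """
    P = np.asarray(partials, dtype=float)
    _check_partials(P)
    K = np.eye(P.shape[0]) - (P - np.diag(np.diag(P)))
    try:
        np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(
            "partial-correlation matrix implies a non-positive-definite structure"
        ) from exc
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _check_partials(P: np.ndarray) -> None:
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ConfigurationError("partials must be a square matrix")
    if not np.allclose(P, P.T):
        raise ConfigurationError("partials must be symmetric")
    if not np.allclose(np.diag(P), 0.0):
        raise ConfigurationError("partials must have a zero diagonal")
    off = P[~np.eye(P.shape[0], dtype=bool)]
    if np.any(np.abs(off) >= 1.0):
        raise ConfigurationError("partial correlations must lie in (-1, 1)")


@dataclass
class GeneratorConfig:
    """Everything needed to generate a deterministic two-wave cohort."""

    n_per_sex: Mapping[str, int]
    true_partials: Mapping[str, np.ndarray]
    margins: Mapping[str, MarginSpec]
    missing_rate: float | Mapping[str, float] = 0.05
    attrition_intercept: float = -1.386  # logit(0.2) dropout
    attrition_age: float = 0.0
    attrition_depression: float = 0.0
    attrition_cognition: float = 0.0
    wave2_shift: Mapping[str, float] = field(default_factory=dict)
    latent_autocorr: float = 0.7
    seed: int = 0
    schema: list[VariableSchema] = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        nodes = network_nodes(self.schema)
        p = len(nodes)
        for sex in SEX_LABELS:
            if sex not in self.n_per_sex:
                raise ConfigurationError(f"n_per_sex missing {sex!r}")
            if self.n_per_sex[sex] < 1:
                raise ConfigurationError(f"n_per_sex[{sex!r}] must be positive")
            if sex not in self.true_partials:
                raise ConfigurationError(f"true_partials missing {sex!r}")
            P = np.asarray(self.true_partials[sex], dtype=float)
            if P.shape != (p, p):
                raise ConfigurationError(f"true_partials[{sex!r}] must be {p}x{p}")
            correlation_from_partials(P)  # validates symmetry / PD
        for name in nodes:
            if name not in self.margins:
                raise ConfigurationError(f"margins missing variable {name!r}")
        for rate in self._rates(nodes).values():
            if not 0.0 <= rate < 1.0:
                raise ConfigurationError(f"missing_rate must be in [0, 1): {rate}")
        if not 0.0 <= self.latent_autocorr <= 1.0:
            raise ConfigurationError("latent_autocorr must be in [0, 1]")

    def _rates(self, nodes: list[str]) -> dict[str, float]:
        if isinstance(self.missing_rate, Mapping):
            return {n: float(self.missing_rate.get(n, 0.0)) for n in nodes}
        return {n: float(self.missing_rate) for n in nodes}


def true_network(config: GeneratorConfig, sex: str) -> np.ndarray:
    """Ground-truth partial-correlation matrix for one sex."""
    if sex not in SEX_LABELS:
        raise ConfigurationError(f"unknown sex label {sex!r}")
    return np.array(config.true_partials[sex], dtype=float)


_STREAMS = ("latents", "ages", "mcar_w1", "dropout", "wave2_noise", "mcar_w2")


def _sex_rng(config: GeneratorConfig, sex: str, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        [config.seed, SEX_LABELS.index(sex), _STREAMS.index(stream)]
    )


def _latents(config: GeneratorConfig, sex: str) -> np.ndarray:
    """Deterministic wave-1 latent Gaussian rows for one sex stratum."""
    nodes = network_nodes(config.schema)
    R = correlation_from_partials(np.asarray(config.true_partials[sex], dtype=float))
    n = config.n_per_sex[sex]
    rng = _sex_rng(config, sex, "latents")
    chol = np.linalg.cholesky(R)
    return rng.standard_normal((n, len(nodes))) @ chol.T


def _ages(config: GeneratorConfig, sex: str) -> np.ndarray:
    rng = _sex_rng(config, sex, "ages")
    return rng.uniform(70.0, 90.0, size=config.n_per_sex[sex])


def _observed_frame(
    config: GeneratorConfig, sex: str, Z: np.ndarray, ids: list[str], shift: Mapping[str, float]
) -> pd.DataFrame:
    nodes = network_nodes(config.schema)
    data = {}
    for k, name in enumerate(nodes):
        data[name] = config.margins[name].transform(Z[:, k], shift=float(shift.get(name, 0.0)))
    return pd.DataFrame(data, index=ids, columns=nodes, dtype=float)


def _apply_mcar(
    config: GeneratorConfig, sex: str, frame: pd.DataFrame, stream: str
) -> pd.DataFrame:
    rates = config._rates(list(frame.columns))
    rng = _sex_rng(config, sex, stream)
    out = frame.copy()
    for name in frame.columns:
        if rates[name] > 0:
            drop = rng.random(len(frame)) < rates[name]
            out.loc[drop, name] = np.nan
    return out


def generate_wave1(config: GeneratorConfig) -> CohortTable:
    """Generate the baseline cohort for both sexes (deterministic in seed)."""
    frames, sexes, ages, ids_all = [], [], [], []
    for sex in SEX_LABELS:
        Z = _latents(config, sex)
        ids = [f"{sex[0].upper()}{i:04d}" for i in range(config.n_per_sex[sex])]
        frame = _observed_frame(config, sex, Z, ids, shift={})
        frame = _apply_mcar(config, sex, frame, "mcar_w1")
        frames.append(frame)
        ids_all.extend(ids)
        sexes.extend([sex] * len(ids))
        ages.append(_ages(config, sex))
    values = pd.concat(frames)
    return CohortTable(
        subjects=ids_all,
        values=values,
        sex=pd.Series(sexes, index=ids_all),
        age=pd.Series(np.concatenate(ages), index=ids_all),
        wave=1,
        schema=list(config.schema),
    )


def _dropout_probability(config: GeneratorConfig, sex: str) -> np.ndarray:
    """Logistic dropout model on standardized age, depression, cognition."""
    nodes = network_nodes(config.schema)
    Z = _latents(config, sex)
    frame = _observed_frame(config, sex, Z, ids=[str(i) for i in range(len(Z))], shift={})
    age = _ages(config, sex)

    def std(x: np.ndarray) -> np.ndarray:
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    eta = (
        config.attrition_intercept
        + config.attrition_age * std(age)
        + config.attrition_depression * std(frame["depression"].to_numpy())
        + config.attrition_cognition * std(frame["cognition"].to_numpy())
    )
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_attrition(wave1: CohortTable, config: GeneratorConfig) -> CohortTable:
    """Wave-2 table: completer subset with time-varying variables re-drawn.

    Dropout follows the configured logistic model on (true, pre-missingness)
    age, depression and cognition.  Completers' wave-2 latents are
    ``rho * z1 + sqrt(1 - rho^2) * eps`` with fresh correlated noise, so the
    wave-2 marginal latent correlation matches the wave-1 structure; frozen
    traits (education, alcohol, cardiovascular risk, APOE-e4) are copied.
    """
    if wave1.wave != 1:
        raise ConfigurationError("simulate_attrition expects a wave-1 table")
    nodes = network_nodes(config.schema)
    rho = config.latent_autocorr
    frames, sexes, ages, ids_all = [], [], [], []
    for sex in SEX_LABELS:
        n = config.n_per_sex[sex]
        ids = [f"{sex[0].upper()}{i:04d}" for i in range(n)]
        prob = _dropout_probability(config, sex)
        rng = _sex_rng(config, sex, "dropout")
        dropped = rng.random(n) < prob
        keep = ~dropped
        if not keep.any():
            raise DegenerateSimulationError(f"all {sex} subjects dropped out")

        Z1 = _latents(config, sex)
        R = correlation_from_partials(np.asarray(config.true_partials[sex], dtype=float))
        noise_rng = _sex_rng(config, sex, "wave2_noise")
        eps = noise_rng.standard_normal((n, len(nodes))) @ np.linalg.cholesky(R).T
        Z2 = rho * Z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * eps

        frame2 = _observed_frame(config, sex, Z2, ids, shift=config.wave2_shift)
        # frozen traits carry wave-1 observed values
        frozen = [v for v in nodes if v not in TIME_VARYING]
        w1_vals = wave1.values.loc[ids]
        for name in frozen:
            frame2[name] = w1_vals[name].values
        frame2 = _apply_mcar(config, sex, frame2, "mcar_w2")
        for name in frozen:  # do not re-mask frozen traits
            frame2[name] = w1_vals[name].values

        kept_ids = [i for i, k in zip(ids, keep) if k]
        frames.append(frame2.loc[kept_ids])
        ids_all.extend(kept_ids)
        sexes.extend([sex] * len(kept_ids))
        ages.append(wave1.age.loc[kept_ids].to_numpy() + 2.0)
    values = pd.concat(frames)
    return CohortTable(
        subjects=ids_all,
        values=values,
        sex=pd.Series(sexes, index=ids_all),
        age=pd.Series(np.concatenate(ages), index=ids_all),
        wave=2,
        schema=list(config.schema),
    )


def default_margins() -> dict[str, MarginSpec]:
    return {
        "IL6": MarginSpec("zero_inflated_lognormal", p_zero=0.12, log_mu=0.3, log_sigma=0.9),
        "IL8": MarginSpec("zero_inflated_lognormal", p_zero=0.08, log_mu=1.0, log_sigma=0.7),
        "IL10": MarginSpec("zero_inflated_lognormal", p_zero=0.15, log_mu=0.0, log_sigma=1.0),
        "IL12": MarginSpec("zero_inflated_lognormal", p_zero=0.18, log_mu=0.2, log_sigma=1.1),
        "CRP": MarginSpec("zero_inflated_lognormal", p_zero=0.22, log_mu=0.8, log_sigma=1.0),
        "depression": MarginSpec("count_binomialish", n_trials=15, p_success=0.15),
        "cognition": MarginSpec("gaussian", mu=0.0, sigma=1.0),
        "education": MarginSpec("ordinal_cutpoints", cutpoints=(-1.2, -0.4, 0.3, 1.0), range_min=1),
        "alcohol": MarginSpec("ordinal_cutpoints", cutpoints=(-1.0, -0.4, 0.1, 0.7, 1.3), range_min=1),
        "cvd_risk": MarginSpec("gaussian", mu=20.0, sigma=8.0),
        "apoe4": MarginSpec("bernoulli", p=0.35),
    }


def _edges_to_matrix(nodes: list[str], edges: dict[tuple[str, str], float]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    P = np.zeros((len(nodes), len(nodes)))
    for (a, b), w in edges.items():
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w
    return P


def default_scenario(n_per_sex: int = 450, seed: int = 3, missing_rate: float = 0.05) -> GeneratorConfig:
    """Shipped reference scenario: overlapping male/female edge sets with a
    female-only depression-cognition edge of magnitude 0.3.

    Edge magnitudes sit in [0.22, 0.35] so that an n-per-sex of 450 gives
    the estimator a workable signal-to-noise ratio on every margin type
    (binary and heavily tied margins carry roughly half the rank
    information of continuous ones).
    """
    nodes = network_nodes(default_schema())
    shared = {
        ("IL6", "IL8"): 0.33,
        ("IL6", "IL10"): 0.30,
        ("IL6", "IL12"): 0.30,
        ("IL6", "CRP"): 0.26,
        ("IL8", "IL10"): 0.22,
        ("IL10", "IL12"): 0.22,
        ("IL12", "CRP"): 0.22,
        ("education", "cognition"): 0.35,
        ("apoe4", "CRP"): 0.30,
        ("depression", "IL12"): -0.28,
    }
    female = dict(shared)
    female.update({
        ("depression", "cognition"): -0.30,
        ("IL8", "alcohol"): 0.30,
        ("IL6", "depression"): 0.25,
    })
    male = dict(shared)
    male.update({
        ("IL8", "cognition"): -0.30,
        ("CRP", "cvd_risk"): 0.30,
        ("apoe4", "cognition"): -0.22,
    })
    return GeneratorConfig(
        n_per_sex={"female": n_per_sex, "male": n_per_sex},
        true_partials={
            "female": _edges_to_matrix(nodes, female),
            "male": _edges_to_matrix(nodes, male),
        },
        margins=default_margins(),
        missing_rate=missing_rate,
        attrition_intercept=-1.386,
        attrition_age=0.3,
        attrition_depression=0.3,
        attrition_cognition=-0.3,
        seed=seed,
    )
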
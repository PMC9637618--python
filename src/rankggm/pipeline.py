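"""Two-wave analysis orchestration, robustness checks, layout and plotting.

The exploratory step fits one network per sex on the wave-1 table, selects
edges, computes the per-edge female-minus-male posterior differences, and
serializes directional hypotheses.  The confirmatory step re-fits on wave 2
and evaluates each hypothesis by one-sided posterior probability.  All
artifacts are plain CSV/YAML, deterministic in the configured seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.linalg import orthogonal_procrustes

from .cohort import CohortTable, read_cohort_csv, split_by_sex, write_cohort_csv
from .compare import (
    DirectionalHypothesis,
    EdgeDifference,
    differences_to_frame,
    edge_differences,
    form_hypotheses,
    posterior_probability,
    read_hypotheses,
    shared_edge_report,
    write_hypotheses,
)
from .copula import NetworkEstimate, estimate_to_edgelist, gibbs_sample, select_edges
from .errors import InsufficientDataError, RankGGMError
from .simulate import GeneratorConfig, generate_wave1, simulate_attrition

logger = logging.getLogger("rankggm")

__all__ = [
    "AnalysisConfig",
    "WaveReport",
    "run_exploratory",
    "run_confirmatory",
    "paired_wave_ttest",
    "compare_completers",
    "fr_layout_averaged",
    "render_network_figure",
]

GROUPS = ("female", "male")  # differences are always female minus male


@dataclass
class AnalysisConfig:
    """Settings for one wave's analysis run."""

    n_draws: int = 5000
    burn_in: int = 500
    thin: int = 1
    seed_female: int = 11
    seed_male: int = 12
    level: float = 0.95
    pp_threshold: float = 0.95
    out_dir: Path | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if not 0.0 < self.pp_threshold < 1.0:
            raise ValueError("pp_threshold must be in (0, 1)")

    def to_meta(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "burn_in": self.burn_in,
            "thin": self.thin,
            "seed_female": self.seed_female,
            "seed_male": self.seed_male,
            "level": self.level,
            "pp_threshold": self.pp_threshold,
        }


@dataclass
class WaveReport:
    """Everything produced by one wave's analysis."""

    wave: int
    estimates: dict  # sex -> NetworkEstimate
    samples: dict    # sex -> PosteriorSample
    differences: list[EdgeDifference]
    hypotheses: list[DirectionalHypothesis]
    layout: dict     # node -> (x, y)
    hypothesis_file_sha256: str | None = None
    summary: pd.DataFrame | None = None


def _fit_both(table: CohortTable, config: AnalysisConfig):
    try:
        female, male = split_by_sex(table)
    except RankGGMError as exc:
        raise type(exc)(f"[split_by_sex] {exc}") from exc
    samples, estimates = {}, {}
    for sex, sub, seed in (
        ("female", female, config.seed_female),
        ("male", male, config.seed_male),
    ):
        logger.info("fitting %s stratum (n=%d, seed=%d)", sex, sub.n_subjects, seed)
        try:
            samples[sex] = gibbs_sample(
                sub,
                n_draws=config.n_draws,
                burn_in=config.burn_in,
                thin=config.thin,
                seed=seed,
            )
            estimates[sex] = select_edges(samples[sex], level=config.level)
        except RankGGMError as exc:
            raise type(exc)(f"[gibbs_sample:{sex}] {exc}") from exc
    return samples, estimates


def _write_artifacts(report: WaveReport, config: AnalysisConfig, prefix: str) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sex, est in report.estimates.items():
        estimate_to_edgelist(est).to_csv(out / f"{prefix}_edges_{sex}.csv", index=False)
    differences_to_frame(report.differences).to_csv(
        out / f"{prefix}_differences_female_minus_male.csv", index=False
    )
    layout_df = pd.DataFrame(
        [(n, xy[0], xy[1]) for n, xy in report.layout.items()],
        columns=["node", "x", "y"],
    )
    layout_df.to_csv(out / f"{prefix}_layout.csv", index=False)
    with open(out / f"{prefix}_meta.yaml", "w") as fh:
        yaml.safe_dump({"wave": report.wave, **config.to_meta()}, fh, sort_keys=False)


def run_exploratory(table: CohortTable, config: AnalysisConfig) -> WaveReport:
    """Wave-1 analysis: fit per sex, select, compare, form hypotheses."""
    samples, estimates = _fit_both(table, config)
    diffs = edge_differences(
        samples["female"], samples["male"], n_draws=config.n_draws, level=config.level
    )
    hyps = form_hypotheses(diffs)
    layout = fr_layout_averaged(
        [estimates["female"], estimates["male"]], seed=config.seed_female
    )
    report = WaveReport(
        wave=table.wave,
        estimates=estimates,
        samples=samples,
        differences=diffs,
        hypotheses=hyps,
        layout=layout,
    )
    _write_artifacts(report, config, "exploratory")
    if config.out_dir is not None:
        sha = write_hypotheses(
            hyps,
            Path(config.out_dir) / "hypotheses.yaml",
            groups=GROUPS,
            meta=config.to_meta(),
        )
        report.hypothesis_file_sha256 = sha
    return report


def run_confirmatory(
    table: CohortTable,
    config: AnalysisConfig,
    hypotheses: list[DirectionalHypothesis] | str | Path,
    exploratory: WaveReport | None = None,
) -> WaveReport:
    """Wave-2 analysis: re-fit per sex and test each carried-forward hypothesis."""
    sha = None
    if isinstance(hypotheses, (str, Path)):
        hypotheses, _meta, sha = read_hypotheses(hypotheses)
    samples, estimates = _fit_both(table, config)
    diffs = edge_differences(
        samples["female"], samples["male"], n_draws=config.n_draws, level=config.level
    )
    tested = [
        posterior_probability(
            samples["female"], samples["male"], h, threshold=config.pp_threshold
        )
        for h in hypotheses
    ]
    layout = fr_layout_averaged(
        [estimates["female"], estimates["male"]], seed=config.seed_female
    )
    summary = summary_table(
        exploratory.estimates if exploratory else None, estimates, tested
    )
    report = WaveReport(
        wave=table.wave,
        estimates=estimates,
        samples=samples,
        differences=diffs,
        hypotheses=tested,
        layout=layout,
        hypothesis_file_sha256=sha,
        summary=summary,
    )
    _write_artifacts(report, config, "confirmatory")
    if config.out_dir is not None:
        out = Path(config.out_dir)
        pd.DataFrame(
            {
                "node_i": [h.edge[0] for h in tested],
                "node_j": [h.edge[1] for h in tested],
                "direction": [
                    "female>male" if h.direction == 1 else "female<male" for h in tested
                ],
                "pp": [h.pp for h in tested],
                "confirmed": [h.confirmed for h in tested],
            }
        ).to_csv(out / "confirmations.csv", index=False)
        summary.to_csv(out / "summary_table.csv", index=False)
        (out / "summary_table.md").write_text(summary.to_markdown(index=False))
    return report


def summary_table(
    exploratory_estimates: dict | None,
    confirmatory_estimates: dict,
    tested: list[DirectionalHypothesis],
) -> pd.DataFrame:
    """Per-edge cross-wave summary of selection and confirmation outcomes."""
    est_f = confirmatory_estimates["female"]
    nodes = est_f.nodes
    tested_map = {tuple(sorted(h.edge)): h for h in tested}
    rows = []
    for i, j in zip(*np.triu_indices(len(nodes), 1)):
        edge = (nodes[i], nodes[j])
        key = tuple(sorted(edge))
        h = tested_map.get(key)
        row = {
            "node_i": edge[0],
            "node_j": edge[1],
            "wave2_female": bool(confirmatory_estimates["female"].adjacency[i, j]),
            "wave2_male": bool(confirmatory_estimates["male"].adjacency[i, j]),
            "hypothesis": (
                ("female>male" if h.direction == 1 else "female<male") if h else ""
            ),
            "pp": h.pp if h else np.nan,
            "confirmed": h.confirmed if h else None,
        }
        if exploratory_estimates is not None:
            row["wave1_female"] = bool(exploratory_estimates["female"].adjacency[i, j])
            row["wave1_male"] = bool(exploratory_estimates["male"].adjacency[i, j])
        rows.append(row)
    return pd.DataFrame(rows)


# -- robustness checks -----------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    variable: str
    n_pairs: int
    t: float
    df: int
    p_value: float
    cohens_d: float
    degenerate: bool = False


def paired_wave_ttest(
    wave1: CohortTable, wave2: CohortTable, variable: str
) -> PairedTestResult:
    """Paired t-test on subject-matched values of one variable across waves.

    Effect size is paired Cohen's d = mean(diff) / SD(diff).  A zero-variance
    nonzero difference is reported with a ``degenerate`` flag (p -> 0)
    rather than raising.
    """
    shared = [s for s in wave1.subjects if s in set(wave2.subjects)]
    x1 = wave1.values.loc[shared, variable]
    x2 = wave2.values.loc[shared, variable]
    ok = x1.notna() & x2.notna()
    x1, x2 = x1[ok].to_numpy(), x2[ok].to_numpy()
    n = x1.size
    if n < 2:
        raise InsufficientDataError(
            f"{variable}: only {n} complete pair(s) across waves"
        )
    diff = x2 - x1
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedTestResult(variable, n, 0.0, n - 1, 1.0, 0.0)
        return PairedTestResult(
            variable, n, np.inf if diff.mean() > 0 else -np.inf, n - 1, 0.0,
            np.inf if diff.mean() > 0 else -np.inf, degenerate=True,
        )
    t, p = stats.ttest_rel(x2, x1)
    return PairedTestResult(
        variable, n, float(t), n - 1, float(p), float(diff.mean() / sd)
    )


def compare_completers(
    wave1: CohortTable, completer_flag: pd.Series
) -> pd.DataFrame:
    """Baseline comparison of wave-2 completers versus non-completers.

    Continuous variables: Welch t-test + Cohen's d (pooled SD).  Ordinal /
    skewed variables: Wilcoxon rank-sum with mean ranks (d on raw values is
    reported alongside).  Binary variables and sex: chi-square test.
    """
    flags = completer_flag.reindex(wave1.subjects)
    if flags.isna().any():
        raise ValueError("completer_flag must cover every wave-1 subject")
    comp = flags.astype(bool)
    if comp.all() or (~comp).all():
        raise InsufficientDataError("both completer groups must be non-empty")

    rows = []
    columns = {"age": "continuous"}
    for v in wave1.schema:
        columns[v.name] = v.level
    columns["depression"] = "ordinal"

    def values_of(name: str) -> pd.Series:
        return wave1.age if name == "age" else wave1.values[name]

    for name, level in columns.items():
        col = values_of(name)
        a = col[comp.values].dropna().to_numpy()  # completers
        b = col[~comp.values].dropna().to_numpy()
        row = {
            "variable": name,
            "n_completers": a.size,
            "n_noncompleters": b.size,
            "mean_completers": a.mean() if a.size else np.nan,
            "mean_noncompleters": b.mean() if b.size else np.nan,
        }
        if a.size < 2 or b.size < 2:
            raise InsufficientDataError(f"{name}: a group has < 2 observed values")
        if level == "continuous":
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row.update(test="welch_t", statistic=float(t), p_value=float(p),
                       cohens_d=_pooled_d(a, b))
        elif level == "ordinal":
            row.update(_rank_sum(a, b))
            row["cohens_d"] = _pooled_d(a, b)
        else:  # binary
            tab = pd.crosstab(comp.values, col)
            chi2, p, _, _ = stats.chi2_contingency(tab)
            row.update(test="chi_square", statistic=float(chi2), p_value=float(p),
                       cohens_d=np.nan)
        rows.append(row)

    # sex composition
    tab = pd.crosstab(comp.values, wave1.sex.values)
    chi2, p, _, _ = stats.chi2_contingency(tab)
    rows.append({
        "variable": "sex", "n_completers": int(comp.sum()),
        "n_noncompleters": int((~comp).sum()), "mean_completers": np.nan,
        "mean_noncompleters": np.nan, "test": "chi_square",
        "statistic": float(chi2), "p_value": float(p), "cohens_d": np.nan,
    })
    return pd.DataFrame(rows)


def _pooled_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _rank_sum(a: np.ndarray, b: np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum with mean ranks; exact p for small n without ties."""
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    mean_rank_a = float(ranks[: a.size].mean())
    mean_rank_b = float(ranks[a.size :].mean())
    method = "exact" if (a.size + b.size <= 25 and np.unique(combined).size == combined.size) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "test": f"rank_sum_{method}",
        "statistic": float(u),
        "p_value": float(p),
        "mean_rank_completers": mean_rank_a,
        "mean_rank_noncompleters": mean_rank_b,
    }


# -- layout and plotting ---------------------------------------------------


def _single_layout(est: NetworkEstimate, seed: int) -> np.ndarray:
    g = nx.Graph()
    g.add_nodes_from(est.nodes)
    p = len(est.nodes)
    for i, j in zip(*np.triu_indices(p, 1)):
        if est.adjacency[i, j]:
            g.add_edge(est.nodes[i], est.nodes[j], weight=abs(est.selected_partials[i, j]))
    pos = nx.spring_layout(g, weight="weight", seed=seed)
    return np.array([pos[n] for n in est.nodes])


def fr_layout_averaged(estimates: list[NetworkEstimate], seed: int = 0) -> dict:
    """Force-directed layout per network, Procrustes-aligned, then averaged.

    All estimates must share a node set; the result maps node name to an
    (x, y) coordinate and is deterministic at fixed seed.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    nodes = list(estimates[0].nodes)
    if not nodes:
        raise ValueError("empty node set")
    for est in estimates[1:]:
        if list(est.nodes) != nodes:
            raise ValueError("all estimates must share a node set")
    layouts = [_single_layout(est, seed) for est in estimates]
    ref = layouts[0] - layouts[0].mean(axis=0)
    aligned = [ref]
    for lay in layouts[1:]:
        cur = lay - lay.mean(axis=0)
        if np.allclose(cur, 0) or np.allclose(ref, 0):
            aligned.append(cur)
            continue
        R, scale = orthogonal_procrustes(cur, ref)
        norm = (cur**2).sum()
        aligned.append(cur @ R * (scale / norm if norm > 0 else 1.0))
    avg = np.mean(aligned, axis=0)
    return {n: (float(x), float(y)) for n, (x, y) in zip(nodes, avg)}


def render_network_figure(
    estimate: NetworkEstimate, layout: dict, path
) -> dict:
    """Draw the selected network: blue positive, red negative, width ~ |partial|.

    Returns metadata including the number of edges drawn.
    """
    missing = [n for n in estimate.nodes if n not in layout]
    if missing:
        raise ValueError(f"layout missing nodes {missing}")
    fig, ax = plt.subplots(figsize=(6, 6))
    p = len(estimate.nodes)
    n_edges = 0
    for i, j in zip(*np.triu_indices(p, 1)):
        if not estimate.adjacency[i, j]:
            continue
        w = estimate.selected_partials[i, j]
        xi, yi = layout[estimate.nodes[i]]
        xj, yj = layout[estimate.nodes[j]]
        ax.plot(
            [xi, xj], [yi, yj],
            color="tab:blue" if w > 0 else "tab:red",
            linewidth=1.0 + 8.0 * abs(w),
            alpha=min(1.0, 0.35 + abs(w)),
            zorder=1,
        )
        n_edges += 1
    xs = [layout[n][0] for n in estimate.nodes]
    ys = [layout[n][1] for n in estimate.nodes]
    ax.scatter(xs, ys, s=900, c="white", edgecolors="black", zorder=2)
    for n in estimate.nodes:
        ax.annotate(n, layout[n], ha="center", va="center", fontsize=7, zorder=3)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return {"path": str(path), "n_edges": n_edges, "n_nodes": p}


# -- simulation entry points ----------------------------------------------


def simulate_two_waves(config: GeneratorConfig) -> tuple[CohortTable, CohortTable]:
    """Convenience wrapper: wave 1 plus attrition-thinned wave 2."""
    w1 = generate_wave1(config)
    w2 = simulate_attrition(w1, config)
    return w1, w2
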
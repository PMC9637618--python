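"""Posterior comparison of two group networks.

Difference distributions pair draws index-by-index across the two
independent chains, keeping the Monte-Carlo sample size equal to the draw
count.  Directional hypotheses are confirmed when the one-sided posterior
probability exceeds the threshold; exact ties between paired draws
contribute one half, so pp(direction) + pp(opposite) == 1 exactly.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .copula import NetworkEstimate, PosteriorSample, equal_tailed_ci
from .errors import ComparisonError

__all__ = [
    "EdgeDifference",
    "DirectionalHypothesis",
    "edge_differences",
    "form_hypotheses",
    "posterior_probability",
    "shared_edge_report",
    "differences_to_frame",
    "write_hypotheses",
    "read_hypotheses",
]


@dataclass(frozen=True)
class EdgeDifference:
    """Posterior difference (group A minus group B) for one edge."""

    edge: tuple[str, str]
    mean_diff: float
    ci_lower: float
    ci_upper: float
    significant: bool
    n_draws: int


@dataclass(frozen=True)
class DirectionalHypothesis:
    """A signed claim about one edge: direction +1 means A > B, -1 means A < B."""

    edge: tuple[str, str]
    direction: int
    exploratory_mean_diff: float = float("nan")
    pp: float = float("nan")
    confirmed: bool | None = None

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")


def _check_nodes(a: PosteriorSample | NetworkEstimate, b: PosteriorSample | NetworkEstimate) -> None:
    if list(a.nodes) != list(b.nodes):
        raise ComparisonError(f"node sets differ: {a.nodes} vs {b.nodes}")


def _paired_diffs(
    sample_a: PosteriorSample, sample_b: PosteriorSample, n_draws: int | None
) -> np.ndarray:
    """(n, p, p) array of index-paired draw differences, A minus B."""
    _check_nodes(sample_a, sample_b)
    avail = min(sample_a.n_draws, sample_b.n_draws)
    if n_draws is None:
        n = avail
    elif n_draws > avail:
        warnings.warn(
            f"requested {n_draws} draws but only {avail} available; using {avail}",
            stacklevel=3,
        )
        n = avail
    else:
        n = n_draws
    return sample_a.partials[:n] - sample_b.partials[:n]


def edge_differences(
    sample_a: PosteriorSample,
    sample_b: PosteriorSample,
    n_draws: int | None = 5000,
    level: float = 0.95,
) -> list[EdgeDifference]:
    """Per-edge posterior mean difference (A - B) with equal-tailed CI."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1): {level}")
    diffs = _paired_diffs(sample_a, sample_b, n_draws)
    nodes = list(sample_a.nodes)
    p = len(nodes)
    out = []
    for i, j in zip(*np.triu_indices(p, 1)):
        d = diffs[:, i, j]
        lo, hi = equal_tailed_ci(d, level)
        out.append(
            EdgeDifference(
                edge=(nodes[i], nodes[j]),
                mean_diff=float(d.mean()),
                ci_lower=float(lo),
                ci_upper=float(hi),
                significant=bool(lo > 0.0 or hi < 0.0),
                n_draws=d.size,
            )
        )
    return out


def form_hypotheses(differences: list[EdgeDifference]) -> list[DirectionalHypothesis]:
    """One directional hypothesis per significant exploratory difference."""
    return [
        DirectionalHypothesis(
            edge=d.edge,
            direction=1 if d.mean_diff > 0 else -1,
            exploratory_mean_diff=d.mean_diff,
        )
        for d in differences
        if d.significant
    ]


def posterior_probability(
    sample_a: PosteriorSample,
    sample_b: PosteriorSample,
    hypothesis: DirectionalHypothesis,
    threshold: float = 0.95,
    n_draws: int | None = None,
) -> DirectionalHypothesis:
    """Fraction of paired draws supporting the hypothesized inequality.

    Ties contribute one half each, so pp(d) + pp(-d) == 1 exactly.
    Confirmation requires pp strictly above ``threshold``.
    """
    _check_nodes(sample_a, sample_b)
    nodes = list(sample_a.nodes)
    for name in hypothesis.edge:
        if name not in nodes:
            raise ComparisonError(f"edge node {name!r} not in node set")
    i, j = (nodes.index(hypothesis.edge[0]), nodes.index(hypothesis.edge[1]))
    diffs = _paired_diffs(sample_a, sample_b, n_draws)[:, i, j] * hypothesis.direction
    n = diffs.size
    pp = (np.count_nonzero(diffs > 0) + 0.5 * np.count_nonzero(diffs == 0)) / n
    return replace(hypothesis, pp=float(pp), confirmed=bool(pp > threshold))


def shared_edge_report(est_a: NetworkEstimate, est_b: NetworkEstimate) -> pd.DataFrame:
    """Classify every unordered edge as both / A-only / B-only / neither."""
    _check_nodes(est_a, est_b)
    nodes = list(est_a.nodes)
    p = len(nodes)
    rows = []
    for i, j in zip(*np.triu_indices(p, 1)):
        in_a = bool(est_a.adjacency[i, j])
        in_b = bool(est_b.adjacency[i, j])
        label = (
            "both" if in_a and in_b
            else "A-only" if in_a
            else "B-only" if in_b
            else "neither"
        )
        rows.append(
            {
                "node_i": nodes[i],
                "node_j": nodes[j],
                "label": label,
                "partial_a": est_a.selected_partials[i, j],
                "partial_b": est_b.selected_partials[i, j],
            }
        )
    return pd.DataFrame(rows)


def differences_to_frame(differences: list[EdgeDifference]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node_i": [d.edge[0] for d in differences],
            "node_j": [d.edge[1] for d in differences],
            "mean_diff": [d.mean_diff for d in differences],
            "ci_lower": [d.ci_lower for d in differences],
            "ci_upper": [d.ci_upper for d in differences],
            "significant": [d.significant for d in differences],
        }
    )


def write_hypotheses(
    hypotheses: list[DirectionalHypothesis],
    path,
    groups: tuple[str, str] = ("female", "male"),
    meta: dict | None = None,
) -> str:
    """Serialize hypotheses to YAML; returns the content's sha256 for linking."""
    payload = {
        "groups": list(groups),
        "meta": meta or {},
        "hypotheses": [
            {
                "edge": list(h.edge),
                "direction": int(h.direction),
                "exploratory_mean_diff": float(h.exploratory_mean_diff),
            }
            for h in hypotheses
        ],
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    with open(path, "w") as fh:
        fh.write(text)
    return hashlib.sha256(text.encode()).hexdigest()


def read_hypotheses(path) -> tuple[list[DirectionalHypothesis], dict, str]:
    """Load hypotheses; returns (hypotheses, metadata, content sha256)."""
    with open(path) as fh:
        text = fh.read()
    try:
        payload = yaml.safe_load(text)
        items = payload["hypotheses"]
    except Exception as exc:
        raise ComparisonError(f"corrupt hypothesis file {path}: {exc}") from exc
    hyps = [
        DirectionalHypothesis(
            edge=tuple(item["edge"]),
            direction=int(item["direction"]),
            exploratory_mean_diff=float(item.get("exploratory_mean_diff", float("nan"))),
        )
        for item in items
    ]
    return hyps, payload, hashlib.sha256(text.encode()).hexdigest()
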
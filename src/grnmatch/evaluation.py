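"""Precision-recall evaluation of edge rankings against a known network.

Edges are ranked by confidence weight; equal-weight edges form tied groups
that are admitted jointly.  The area under the precision-recall curve is
computed as step-wise average precision, ``sum_k (R_k - R_{k-1}) P_k`` over
tied groups, which avoids the optimism of linear interpolation in PR space.
The random baseline equals true-edge prevalence |truth| / |candidates| —
the expected average precision of a uniformly random ranking.

Three inference aims are supported: typed directed edges (T), directed
edges (D) and undirected edges (U).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Set, Union

import numpy as np

from .scoring import EdgeWeightTable
from .topology import GroundTruthNetwork

__all__ = ["PRCurve", "ground_truth_edges", "pr_curve", "aupr", "random_baseline",
           "plot_pr_curve"]


@dataclass
class PRCurve:
    """Precision/recall at each distinct-weight threshold (descending)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    prevalence: float

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        self.recall = np.asarray(self.recall, dtype=float)
        if np.any(np.diff(self.recall) < -1e-12):
            raise ValueError("recall must be non-decreasing")


def ground_truth_edges(truth: GroundTruthNetwork, aim: str) -> Set[tuple]:
    """True-edge set keyed like the EdgeWeightTable entries for ``aim``."""
    if aim == "typed":
        if any(e.itype is None for e in truth.edges):
            raise ValueError("typed aim requires a fully typed ground truth")
        return {(e.parent, e.child, e.itype) for e in truth.edges}
    if aim == "directed":
        return {(e.parent, e.child) for e in truth.edges}
    if aim == "undirected":
        return {(min(e.parent, e.child), max(e.parent, e.child)) for e in truth.edges}
    raise ValueError(f"unknown aim {aim!r}")


def pr_curve(weights: EdgeWeightTable, truth_edges: Set[tuple]) -> PRCurve:
    """Tied-group precision-recall curve of an edge ranking."""
    if not truth_edges:
        raise ValueError("ground truth must contain at least one edge")
    missing = truth_edges - set(weights.entries)
    if missing:
        raise ValueError(f"true edges outside the candidate domain: {missing}")
    items = sorted(weights.entries.items(), key=lambda kv: -kv[1])
    n_true = len(truth_edges)
    thresholds, precision, recall = [], [], []
    tp = 0
    seen = 0
    i = 0
    while i < len(items):
        w = items[i][1]
        j = i
        while j < len(items) and items[j][1] == w:
            if items[j][0] in truth_edges:
                tp += 1
            seen += 1
            j += 1
        thresholds.append(w)
        precision.append(tp / seen)
        recall.append(tp / n_true)
        i = j
    return PRCurve(
        thresholds=np.array(thresholds),
        precision=np.array(precision),
        recall=np.array(recall),
        prevalence=n_true / len(items),
    )


def aupr(curve: PRCurve) -> float:
    """Step-wise average precision over tied threshold groups."""
    r = np.concatenate([[0.0], curve.recall])
    return float(np.sum(np.diff(r) * curve.precision))


def random_baseline(truth_edges: Set[tuple], candidate_domain) -> float:
    """Expected average precision of a random ranking: prevalence."""
    n = len(candidate_domain)
    if n == 0:
        raise ValueError("candidate domain must be nonempty")
    return len(truth_edges) / n


def evaluate(weights: EdgeWeightTable, truth: GroundTruthNetwork) -> dict:
    """AUPR, baseline and curve points for one edge-weight table."""
    te = ground_truth_edges(truth, weights.aim)
    curve = pr_curve(weights, te)
    return {
        "aim": weights.aim,
        "aupr": aupr(curve),
        "baseline": random_baseline(te, weights.entries),
        "precision": curve.precision.tolist(),
        "recall": curve.recall.tolist(),
        "thresholds": curve.thresholds.tolist(),
    }


def plot_pr_curve(curve: PRCurve, path: Union[str, "Path"], title: str = "") -> None:
    """Save a simple step plot of the PR curve (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[curve.precision[0]], curve.precision])
    ax.step(r, p, where="post")
    ax.axhline(curve.prevalence, ls="--", color="grey", label="random baseline")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
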
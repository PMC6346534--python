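"""BIC model averaging: Schwarz weights and per-edge confidence weights.

Candidate fits are converted to BIC values — for parametric fits
``BIC = ln(S) G + S ln(dist_L2 / S)`` and for non-parametric fits
``BIC = ln(S) G - 2 ln L_max`` — then, per child gene, to Schwarz weights
``w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2)`` with
``Delta_i = BIC_i - BIC_min``, a BIC-based posterior model probability
under an implicit uniform model prior.  The confidence of an edge is the
summed weight of every candidate model of its child that contains it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Sequence, Tuple, Union

import numpy as np

from .topology import CandidateModel, InteractionType

__all__ = [
    "ScoredModelSet",
    "EdgeWeightTable",
    "bic_parametric",
    "bic_nonparametric",
    "schwarz_weights",
    "score_parametric",
    "score_nonparametric",
    "edge_weights",
]

#: Floor applied to a zero L2 distance before the logarithm; a perfect fit
#: then dominates the weighting as intended instead of producing -inf - inf.
DIST_FLOOR = 1e-300

AIMS = ("typed", "directed", "undirected")


def bic_parametric(S: int, G: int, dist: float) -> float:
    """BIC of a gradient-matched ODE model from its L2 distance."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if not np.isfinite(dist):
        return np.inf
    return float(np.log(S) * G + S * np.log(max(dist, DIST_FLOOR) / S))


def bic_nonparametric(S: int, G: int, loglik: float) -> float:
    """BIC of a non-parametric GP model from its maximised log likelihood."""
    if S < 1:
        raise ValueError("S must be >= 1")
    if not np.isfinite(loglik):
        return np.inf
    return float(np.log(S) * G - 2.0 * loglik)


def schwarz_weights(bics) -> np.ndarray:
    """Normalised Schwarz weights exp(-Delta_i/2) / sum_j exp(-Delta_j/2).

    Computed min-shifted for numerical stability; infinite BICs receive
    weight zero.  Invariant under adding any constant to all BICs.
    """
    b = np.asarray(bics, dtype=float)
    finite = np.isfinite(b)
    if not finite.any():
        raise ValueError("at least one BIC must be finite")
    w = np.zeros_like(b)
    delta = b[finite] - b[finite].min()
    e = np.exp(-delta / 2.0)
    w[finite] = e / e.sum()
    return w


@dataclass
class ScoredModelSet:
    """Per-child candidate models with BIC values and Schwarz weights."""

    child: int
    entries: list  # (CandidateModel, bic, weight)

    def __post_init__(self) -> None:
        total = sum(w for _, _, w in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")


def score_parametric(child: int, fits, S: int) -> ScoredModelSet:
    """Score parametric gradient-match fits of one child gene."""
    bics = [bic_parametric(S, f.n_free_params, f.l2_distance) for f in fits]
    w = schwarz_weights(bics)
    return ScoredModelSet(
        child=child,
        entries=[(f.model, b, wi) for f, b, wi in zip(fits, bics, w)],
    )


def score_nonparametric(child: int, fits, S: int) -> ScoredModelSet:
    """Score non-parametric GP fits of one child gene."""
    bics = [bic_nonparametric(S, f.n_hyperparams, f.max_log_likelihood) for f in fits]
    w = schwarz_weights(bics)
    return ScoredModelSet(
        child=child,
        entries=[(f.model, b, wi) for f, b, wi in zip(fits, bics, w)],
    )


# --------------------------------------------------------------------------
# Edge weights
# --------------------------------------------------------------------------

@dataclass
class EdgeWeightTable:
    """Per-edge confidence weights for one inference aim.

    Keys: typed ``(parent, child, InteractionType)``; directed
    ``(parent, child)``; undirected ``(a, b)`` with ``a < b``.  The domain
    covers every candidate edge for the aim (self-loops excluded), including
    zero-weight ones.
    """

    aim: str
    n_genes: int
    entries: Dict[tuple, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aim not in AIMS:
            raise ValueError(f"unknown aim {self.aim!r}")
        for e, w in self.entries.items():
            if not -1e-9 <= w <= 1.0 + 1e-9:
                raise ValueError(f"edge weight out of [0,1]: {e} -> {w}")

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["parent\tchild\ttype\tweight"]
        for key in sorted(self.entries, key=lambda k: (-self.entries[k], k)):
            if self.aim == "typed":
                p, c, t = key
                lines.append(f"{p}\t{c}\t{t.value}\t{self.entries[key]:.10g}")
            else:
                p, c = key
                lines.append(f"{p}\t{c}\t*\t{self.entries[key]:.10g}")
        Path(path).write_text("\n".join(lines) + "\n")


def _candidate_domain(aim: str, n_genes: int) -> list:
    if aim == "typed":
        return [
            (p, c, t)
            for p in range(n_genes)
            for c in range(n_genes)
            if p != c
            for t in InteractionType
        ]
    if aim == "directed":
        return [(p, c) for p in range(n_genes) for c in range(n_genes) if p != c]
    return [(a, b) for a in range(n_genes) for b in range(a + 1, n_genes)]


def edge_weights(scored: Sequence[ScoredModelSet], aim: str, n_genes: int) -> EdgeWeightTable:
    """Aggregate Schwarz weights into per-edge confidences for an aim.

    Typed weights sum model weights over models containing the typed edge;
    directed weights marginalise over types; undirected weights combine the
    two directed weights by noisy-OR, ``1 - (1 - w_ab)(1 - w_ba)``, since the
    two directions come from different children's (independent) model sets.
    Self-interactions never contribute.
    """
    if not scored:
        raise ValueError("need at least one scored model set")
    directed: Dict[Tuple[int, int], float] = {}
    typed: Dict[Tuple[int, int, InteractionType], float] = {}
    for sms in scored:
        if not sms.entries:
            raise ValueError(f"child {sms.child} has no scored models")
        for m, _, w in sms.entries:
            for e in m.edges():
                directed[(e.parent, e.child)] = directed.get((e.parent, e.child), 0.0) + w
                if e.itype is not None:
                    key = (e.parent, e.child, e.itype)
                    typed[key] = typed.get(key, 0.0) + w
    if aim == "typed":
        if not typed and any(m.edges() for s in scored for m, _, _ in s.entries):
            raise ValueError("typed aim requires typed candidate models")
        entries = {k: min(typed.get(k, 0.0), 1.0) for k in _candidate_domain(aim, n_genes)}
    elif aim == "directed":
        entries = {k: min(directed.get(k, 0.0), 1.0) for k in _candidate_domain(aim, n_genes)}
    elif aim == "undirected":
        entries = {}
        for a, b in _candidate_domain(aim, n_genes):
            wab = min(directed.get((a, b), 0.0), 1.0)
            wba = min(directed.get((b, a), 0.0), 1.0)
            entries[(a, b)] = 1.0 - (1.0 - wab) * (1.0 - wba)
    else:
        raise ValueError(f"unknown aim {aim!r}")
    return EdgeWeightTable(aim=aim, n_genes=n_genes, entries=entries)
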
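"""Network types and candidate-model enumeration for the decoupled system.

Gradient matching treats each gene's rate equation independently given its
candidate parents, so the space of network hypotheses factorises per child
gene: every subset of the other ``N - 1`` genes of size at most ``M``,
optionally crossed with an interaction type (activation/repression) per
parent.  For a 5-gene network with two interaction types this yields 405
candidate models without an in-degree cap, 165 with ``M = 2``, and 55 for
untyped models — a drastic reduction from the ~3.5e9 fully coupled systems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations, product
from math import comb
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

__all__ = [
    "InteractionType",
    "TypedEdge",
    "GroundTruthNetwork",
    "CandidateModel",
    "enumerate_candidate_models",
    "count_candidate_models",
    "count_fully_coupled",
]


class InteractionType(str, Enum):
    """Regulatory interaction type; exactly two values exist (F = 2)."""

    ACTIVATION = "activation"
    REPRESSION = "repression"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Number of alternative interaction types when types are modelled.
N_INTERACTION_TYPES = len(InteractionType)


@dataclass(frozen=True, order=True)
class TypedEdge:
    """A directed regulatory edge, optionally carrying an interaction type."""

    parent: int
    child: int
    itype: Optional[InteractionType] = None

    def untyped(self) -> "TypedEdge":
        return TypedEdge(self.parent, self.child)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A known regulatory network used for simulation and evaluation."""

    n_genes: int
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        pairs = set()
        for e in self.edges:
            if not (0 <= e.parent < self.n_genes and 0 <= e.child < self.n_genes):
                raise ValueError(f"edge {e} endpoint outside [0, {self.n_genes})")
            if (e.parent, e.child) in pairs:
                raise ValueError(f"duplicate edge {e.parent}->{e.child}")
            pairs.add((e.parent, e.child))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: Union[str, Path], gene_names: Optional[Sequence[str]] = None) -> None:
        """Write the network as a ``parent  child  type`` TSV with header."""
        names = gene_names or [f"G{i}" for i in range(self.n_genes)]
        lines = ["parent\tchild\ttype"]
        for e in sorted(self.edges, key=lambda e: (e.parent, e.child)):
            t = e.itype.value if e.itype is not None else "unknown"
            lines.append(f"{names[e.parent]}\t{names[e.child]}\t{t}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], gene_names: Optional[Sequence[str]] = None) -> "GroundTruthNetwork":
        """Read a network TSV; gene names are mapped to 0-based indices.

        If ``gene_names`` is not given, the sorted set of names appearing in
        the file defines the index order.
        """
        rows = []
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:3] != ["parent", "child", "type"]:
                raise ValueError(f"expected header 'parent\\tchild\\ttype', got {header!r}")
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(line.split("\t"))
        if gene_names is None:
            # natural sort so G2 precedes G10
            def key(name: str):
                digits = "".join(ch for ch in name if ch.isdigit())
                return (len(digits) == 0, name.rstrip("0123456789"),
                        int(digits) if digits else 0)

            gene_names = sorted({r[0] for r in rows} | {r[1] for r in rows}, key=key)
        idx = {n: i for i, n in enumerate(gene_names)}
        edges = set()
        for p, c, t in rows:
            itype = None if t == "unknown" else InteractionType(t)
            edges.add(TypedEdge(idx[p], idx[c], itype))
        return cls(n_genes=len(gene_names), edges=frozenset(edges))


@dataclass(frozen=True)
class CandidateModel:
    """One child gene with a candidate parent set (and types, if parametric).

    ``parents`` is an ordered tuple of gene ids sorted ascending; ``itypes``
    is present only for parametric (typed) models and aligns with ``parents``.
    ``includes_self`` marks the forced self-input of non-parametric models and
    is represented as a flag, not a parent entry, so it does not change the
    size of the candidate space.
    """

    child: int
    parents: tuple = ()
    itypes: Optional[tuple] = None
    includes_self: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", tuple(self.parents))
        if self.itypes is not None:
            object.__setattr__(self, "itypes", tuple(self.itypes))
            if len(self.itypes) != len(self.parents):
                raise ValueError("itypes must align with parents")
        if self.child in self.parents:
            raise ValueError("child cannot be its own explicit parent; use includes_self")
        if tuple(sorted(self.parents)) != self.parents:
            raise ValueError("parents must be sorted ascending")

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def typed(self) -> bool:
        return self.itypes is not None

    def edges(self) -> list:
        """Edges asserted by this model (excluding the self-input)."""
        if self.typed:
            return [TypedEdge(p, self.child, t) for p, t in zip(self.parents, self.itypes)]
        return [TypedEdge(p, self.child) for p in self.parents]

    def to_json(self) -> str:
        return json.dumps(
            {
                "child": self.child,
                "parents": list(self.parents),
                "itypes": [t.value for t in self.itypes] if self.itypes is not None else None,
                "includes_self": self.includes_self,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "CandidateModel":
        d = json.loads(s)
        itypes = None
        if d.get("itypes") is not None:
            itypes = tuple(InteractionType(t) for t in d["itypes"])
        return cls(
            child=d["child"],
            parents=tuple(d["parents"]),
            itypes=itypes,
            includes_self=d.get("includes_self", False),
        )


# --------------------------------------------------------------------------
# Enumeration and counting
# --------------------------------------------------------------------------

_TYPE_ORDER = (InteractionType.ACTIVATION, InteractionType.REPRESSION)


def _validate_counts(n_genes: int, n_types: int, max_parents: Optional[int]) -> int:
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    if n_types not in (1, 2):
        raise ValueError("n_types must be 1 or 2")
    if max_parents is None:
        return n_genes - 1
    if not 0 <= max_parents < n_genes:
        raise ValueError("max_parents must satisfy 0 <= M < n_genes (or None)")
    return max_parents


def enumerate_candidate_models(
    n_genes: int,
    n_types: int = 2,
    max_parents: Optional[int] = None,
    typed: bool = True,
    includes_self: bool = False,
) -> dict:
    """Enumerate all candidate models per child gene for the decoupled system.

    For each child gene, all parent subsets of size ``0..max_parents`` drawn
    from the other ``n_genes - 1`` genes are generated in lexicographic order
    of the sorted parent tuple; typed models are crossed with every per-parent
    type assignment (activation before repression). The empty-parent model is
    always included.

    Returns
    -------
    dict
        ``{child: [CandidateModel, ...]}`` with a deterministic ordering.
    """
    m = _validate_counts(n_genes, n_types, max_parents)
    if typed and n_types == 1:
        types: Sequence = (InteractionType.ACTIVATION,)
    else:
        types = _TYPE_ORDER[:n_types]
    out: dict = {}
    for child in range(n_genes):
        others = [g for g in range(n_genes) if g != child]
        models = []
        for size in range(m + 1):
            for parents in combinations(others, size):
                if typed:
                    for assignment in product(types, repeat=size):
                        models.append(
                            CandidateModel(child, parents, assignment, includes_self)
                        )
                else:
                    models.append(CandidateModel(child, parents, None, includes_self))
        out[child] = models
    return out


def count_candidate_models(
    n_genes: int, n_types: int = 2, max_parents: Optional[int] = None
) -> int:
    """Closed-form count of decoupled candidate models: N * sum C(N-1,i) F^i."""
    m = _validate_counts(n_genes, n_types, max_parents)
    per_gene = sum(comb(n_genes - 1, i) * n_types**i for i in range(m + 1))
    return n_genes * per_gene


def count_fully_coupled(n_genes: int, n_types: int = 2) -> int:
    """Count of fully coupled models: the per-gene count raised to the N-th power."""
    _validate_counts(n_genes, n_types, None)
    per_gene = sum(comb(n_genes - 1, i) * n_types**i for i in range(n_genes))
    return per_gene**n_genes
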
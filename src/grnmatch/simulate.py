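"""Hill-kinetics ODE/SDE simulators for benchmark gene-expression data.

Each gene's mRNA concentration follows

    dx_n/dt = s_n + beta_n * f_n(x_parents) - gamma_n * x_n

with basal transcription rate ``s_n``, regulation strength ``beta_n`` and
first-order decay ``gamma_n``.  The regulation function ``f_n`` is the
arithmetic mean of per-parent Hill terms (activation ``x^h/(k^h+x^h)``,
repression ``k^h/(k^h+x^h)``), which keeps ``f_n`` in [0, 1] regardless of
in-degree so that ``beta_n`` retains its meaning as regulation strength.

Three benchmark variants are provided: a deterministic 5-gene network with
eight interactions (non-oscillatory), a 7-interaction variant whose
trajectories oscillate, and a stochastic 10-gene network with process noise
(Euler-Maruyama, multiplicative sqrt(x) diffusion) plus Gaussian
observational noise, emulating the statistical character of realistic
in-silico expression data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .topology import GroundTruthNetwork, InteractionType, TypedEdge

__all__ = [
    "GeneKinetics",
    "ODEModelSpec",
    "ExpressionDataset",
    "hill_term",
    "ode_rhs",
    "simulate_deterministic",
    "simulate_stochastic",
    "make_benchmark_spec",
    "DEFAULT_KINETICS",
]

#: Default kinetic constants for all benchmark specs (stand-in values chosen
#: to give non-trivial dynamics on t in [0, 100]).
DEFAULT_KINETICS = {
    "basal_rate": 0.05,
    "sensitivity": 1.0,
    "decay_rate": 0.3,
    "hill_threshold": 1.0,
    "hill_coefficient": 2.0,
}


class SimulationError(RuntimeError):
    """Raised when numerical integration of a model fails."""


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic parameters of one gene's rate equation."""

    basal_rate: float
    sensitivity: float
    decay_rate: float
    parents: tuple = ()
    itypes: tuple = ()
    hill_thresholds: tuple = ()
    hill_coefficients: tuple = ()

    def __post_init__(self) -> None:
        for name in ("parents", "itypes", "hill_thresholds", "hill_coefficients"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        np_ = len(self.parents)
        if not (len(self.itypes) == len(self.hill_thresholds) == len(self.hill_coefficients) == np_):
            raise ValueError("per-parent fields must align with parents")
        if self.basal_rate < 0 or self.sensitivity < 0:
            raise ValueError("rates must be non-negative")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")
        if any(k <= 0 for k in self.hill_thresholds):
            raise ValueError("hill thresholds must be positive")
        if any(h < 1 for h in self.hill_coefficients):
            raise ValueError("hill coefficients must be >= 1")


@dataclass(frozen=True)
class ODEModelSpec:
    """A complete ODE model: per-gene kinetics plus an initial state."""

    kinetics: tuple
    initial_state: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "kinetics", tuple(self.kinetics))
        x0 = np.asarray(self.initial_state, dtype=float)
        if x0.ndim != 1 or len(x0) != len(self.kinetics):
            raise ValueError("initial_state length must equal gene count")
        if np.any(x0 < 0):
            raise ValueError("initial_state must be non-negative")
        object.__setattr__(self, "initial_state", x0)

    @property
    def n_genes(self) -> int:
        return len(self.kinetics)


@dataclass
class ExpressionDataset:
    """A genes x time-points expression matrix with metadata.

    ``values[g, d]`` is the expression of gene ``g`` at ``times[d]``.
    """

    times: np.ndarray
    values: np.ndarray
    gene_names: list
    truth: Optional[GroundTruthNetwork] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.gene_names), len(self.times)):
            raise ValueError("values must have shape (n_genes, n_times)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write as CSV: first column ``time``, one column per gene."""
        df = pd.DataFrame({"time": self.times})
        for i, name in enumerate(self.gene_names):
            df[name] = self.values[i]
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: Union[str, Path], truth: Optional[GroundTruthNetwork] = None) -> "ExpressionDataset":
        df = pd.read_csv(path)
        if df.columns[0] != "time":
            raise ValueError("first CSV column must be 'time'")
        names = list(df.columns[1:])
        return cls(
            times=df["time"].to_numpy(),
            values=df[names].to_numpy().T,
            gene_names=names,
            truth=truth,
        )


# --------------------------------------------------------------------------
# Dynamics
# --------------------------------------------------------------------------

def hill_term(x: float, threshold: float, coeff: float, itype: InteractionType) -> float:
    """Hill regulation term in [0, 1] (activation x^h/(k^h+x^h), repression k^h/(k^h+x^h))."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("expression level must be non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    xh = x**coeff
    kh = threshold**coeff
    if itype == InteractionType.ACTIVATION:
        return xh / (kh + xh)
    return kh / (kh + xh)


def _regulation(kin: GeneKinetics, state: np.ndarray):
    """Mean of per-parent Hill terms; None when the gene has no parents."""
    if not kin.parents:
        return None
    terms = [
        hill_term(state[p], k, h, it)
        for p, it, k, h in zip(kin.parents, kin.itypes, kin.hill_thresholds, kin.hill_coefficients)
    ]
    return sum(terms) / len(terms)


def ode_rhs(state: np.ndarray, spec: ODEModelSpec) -> np.ndarray:
    """Right-hand side of the network ODE at ``state``."""
    state = np.asarray(state, dtype=float)
    if state.shape != (spec.n_genes,):
        raise ValueError(f"state must have length {spec.n_genes}")
    out = np.empty(spec.n_genes)
    for n, kin in enumerate(spec.kinetics):
        f = _regulation(kin, state)
        reg = kin.sensitivity * f if f is not None else 0.0
        out[n] = kin.basal_rate + reg - kin.decay_rate * state[n]
    return out


def simulate_deterministic(spec: ODEModelSpec, times: Sequence[float]) -> ExpressionDataset:
    """Integrate the ODE system and sample it at ``times``.

    Uses an adaptive Runge-Kutta scheme with relative tolerance 1e-10; raises
    :class:`SimulationError` on integrator failure.  Negative round-off is
    clipped to zero.
    """
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda t, x: ode_rhs(np.maximum(x, 0.0), spec),
        (times[0], times[-1]),
        spec.initial_state,
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise SimulationError(f"ODE integration failed: {sol.message}")
    values = np.maximum(sol.y, 0.0)
    return ExpressionDataset(
        times=times,
        values=values,
        gene_names=[f"G{i}" for i in range(spec.n_genes)],
        provenance={"kind": "deterministic"},
    )


def simulate_stochastic(
    spec: ODEModelSpec,
    times: Sequence[float],
    process_noise_sd: float = 0.1,
    obs_noise_sd: float = 0.05,
    seed: int = 0,
    n_steps: int = 2000,
) -> ExpressionDataset:
    """Euler-Maruyama simulation with sqrt(x) multiplicative process noise.

    The SDE is ``dX = f(X) dt + process_noise_sd * sqrt(X) dW`` with
    reflection at zero; i.i.d. Gaussian observational noise is then added to
    the sampled values and truncated at zero.  Fully reproducible from
    ``seed``.
    """
    if process_noise_sd < 0 or obs_noise_sd < 0:
        raise ValueError("noise parameters must be non-negative")
    times = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    dt = (times[-1] - times[0]) / n_steps
    grid = times[0] + dt * np.arange(n_steps + 1)
    x = spec.initial_state.copy()
    path = np.empty((spec.n_genes, n_steps + 1))
    path[:, 0] = x
    sqrt_dt = np.sqrt(dt)
    for i in range(n_steps):
        drift = ode_rhs(x, spec)
        dw = rng.standard_normal(spec.n_genes) * sqrt_dt
        x = x + drift * dt + process_noise_sd * np.sqrt(np.maximum(x, 0.0)) * dw
        x = np.abs(x)  # reflect at zero
        if not np.all(np.isfinite(x)):
            raise SimulationError("Euler-Maruyama step diverged; reduce dt or noise")
        path[:, i + 1] = x
    # sample the path at the requested observation times
    idx = np.searchsorted(grid, times - 1e-12 * max(1.0, abs(times[-1])))
    idx = np.clip(idx, 0, n_steps)
    clean = path[:, idx]
    noisy = clean + rng.standard_normal(clean.shape) * obs_noise_sd
    noisy = np.maximum(noisy, 0.0)
    return ExpressionDataset(
        times=times,
        values=noisy,
        gene_names=[f"G{i}" for i in range(spec.n_genes)],
        provenance={
            "kind": "stochastic",
            "seed": int(seed),
            "process_noise_sd": process_noise_sd,
            "obs_noise_sd": obs_noise_sd,
        },
    )


# --------------------------------------------------------------------------
# Benchmark specifications
# --------------------------------------------------------------------------

_ACT = InteractionType.ACTIVATION
_REP = InteractionType.REPRESSION

# 7-interaction oscillatory core: a three-gene repressor ring (0 -| 1 -| 2 -| 0)
# driving two downstream reporters.  The 8-interaction non-oscillatory network
# adds the edge 0 -| 2, which closes a double-negative (positive) loop that
# destroys the ring's limit cycle.
_FIVE_GENE_EDGES_7 = [
    (0, 1, _REP),
    (1, 2, _REP),
    (2, 0, _REP),
    (0, 3, _ACT),
    (2, 3, _REP),
    (3, 4, _ACT),
    (1, 4, _REP),
]
_FIVE_GENE_EXTRA_EDGE = (0, 2, _REP)

_FIVE_GENE_X0 = np.array([1.5, 0.2, 0.6, 0.4, 0.8])


def _spec_from_edges(
    edges,
    n_genes: int,
    x0: np.ndarray,
    hill_coeff: float = DEFAULT_KINETICS["hill_coefficient"],
    steep_edges: Optional[set] = None,
) -> ODEModelSpec:
    steep_edges = steep_edges or set()
    kinetics = []
    for child in range(n_genes):
        incoming = [(p, t) for (p, c, t) in edges if c == child]
        incoming.sort()
        coeffs = tuple(
            4.0 if (p, child) in steep_edges else hill_coeff for p, _ in incoming
        )
        kinetics.append(
            GeneKinetics(
                basal_rate=DEFAULT_KINETICS["basal_rate"],
                sensitivity=DEFAULT_KINETICS["sensitivity"],
                decay_rate=DEFAULT_KINETICS["decay_rate"],
                parents=tuple(p for p, _ in incoming),
                itypes=tuple(t for _, t in incoming),
                hill_thresholds=tuple(DEFAULT_KINETICS["hill_threshold"] for _ in incoming),
                hill_coefficients=coeffs,
            )
        )
    return ODEModelSpec(kinetics=tuple(kinetics), initial_state=x0)


def _truth_from_edges(edges, n_genes: int) -> GroundTruthNetwork:
    return GroundTruthNetwork(
        n_genes=n_genes,
        edges=frozenset(TypedEdge(p, c, t) for p, c, t in edges),
    )


def make_benchmark_spec(variant: str, seed: int = 0):
    """Build one of the benchmark (ODEModelSpec, GroundTruthNetwork) pairs.

    Variants
    --------
    ``non_oscillatory_5``
        5 genes, 8 typed interactions; trajectories relax to a fixed point.
    ``oscillatory_5``
        The same network with one edge removed (7 interactions) and steeper
        Hill coefficients (h = 4) on the repressor ring, producing sustained
        oscillations.
    ``stochastic_10``
        10 genes, 10 typed interactions drawn reproducibly from ``seed``.
    """
    if variant == "non_oscillatory_5":
        edges = _FIVE_GENE_EDGES_7 + [_FIVE_GENE_EXTRA_EDGE]
        return _spec_from_edges(edges, 5, _FIVE_GENE_X0), _truth_from_edges(edges, 5)
    if variant == "oscillatory_5":
        ring = {(0, 1), (1, 2), (2, 0)}
        spec = _spec_from_edges(_FIVE_GENE_EDGES_7, 5, _FIVE_GENE_X0, steep_edges=ring)
        return spec, _truth_from_edges(_FIVE_GENE_EDGES_7, 5)
    if variant == "stochastic_10":
        rng = np.random.default_rng(seed)
        n = 10
        pairs = [(p, c) for p in range(n) for c in range(n) if p != c]
        chosen = rng.choice(len(pairs), size=10, replace=False)
        edges = [
            (pairs[i][0], pairs[i][1], _ACT if rng.random() < 0.5 else _REP)
            for i in sorted(chosen)
        ]
        x0 = rng.uniform(0.2, 1.5, size=n)
        return _spec_from_edges(edges, n, x0), _truth_from_edges(edges, n)
    raise ValueError(f"unknown benchmark variant {variant!r}")


def default_times(variant: str, n_points: Optional[int] = None) -> np.ndarray:
    """Default observation grids: 21/41 points on [0, 100] (5-gene), 20 (10-gene)."""
    if variant == "stochastic_10":
        return np.linspace(0.0, 100.0, n_points or 20)
    return np.linspace(0.0, 100.0, n_points or 21)
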
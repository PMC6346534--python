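"""Non-parametric gradient matching: GP regression of derivatives on parents.

Each gene's smoothed derivative is modelled as a GP function of the smoothed
expression levels of its candidate parents and, always, of the gene itself
(first-order decay makes self-dependence ubiquitous, and the forced
self-input does not change the size of the candidate space).  The covariance
is a squared exponential over the input (expression) space with one
automatic-relevance-determination lengthscale per input dimension, letting
the likelihood shrink away irrelevant parents.  Candidates are scored by the
maximised marginal likelihood; the hyperparameter count G is
(|parents| + 1) ARD lengthscales plus signal and noise amplitudes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .gp import GPFitError, JITTER, SmoothedTrajectories
from .topology import CandidateModel

__all__ = ["NonparametricFit", "ard_log_marginal_likelihood", "fit_nonparametric",
           "fit_all_nonparametric"]

#: ARD lengthscale bounds on standardised inputs.
ARD_LENGTHSCALE_BOUNDS = (1e-2, 1e3)


@dataclass
class NonparametricFit:
    """A scored non-parametric candidate: ARD hyperparameters and likelihood."""

    model: CandidateModel
    lengthscales: np.ndarray  # one per input dimension (self first)
    signal_sd: float
    noise_sd: float
    max_log_likelihood: float

    @property
    def n_hyperparams(self) -> int:
        return len(self.lengthscales) + 2


def _ard_kernel(X: np.ndarray, lengthscales: np.ndarray, signal_sd: float) -> np.ndarray:
    """SE-ARD kernel over rows of X (S x P)."""
    Z = X / lengthscales
    sq = np.sum(Z**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    return signal_sd**2 * np.exp(-0.5 * np.maximum(d2, 0.0))


def ard_log_marginal_likelihood(
    y: np.ndarray, X: np.ndarray, lengthscales, signal_sd: float, noise_sd: float
) -> float:
    """Zero-mean GP log marginal likelihood with an SE-ARD kernel."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = _ard_kernel(X, np.asarray(lengthscales, dtype=float), signal_sd)
    k[np.diag_indices_from(k)] += noise_sd**2 + JITTER * signal_sd**2
    try:
        cf = cho_factor(k, lower=True)
    except np.linalg.LinAlgError as exc:
        raise GPFitError("ARD kernel matrix not PSD") from exc
    alpha = cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * len(y) * np.log(2.0 * np.pi))


def fit_nonparametric(
    model: CandidateModel,
    smoothed: SmoothedTrajectories,
    restarts: int = 5,
    seed: int = 0,
) -> NonparametricFit:
    """Maximise the ARD-GP marginal likelihood of the child's derivatives.

    Inputs are the child's own smoothed expression followed by its candidate
    parents', standardised per dimension; targets are the centred smoothed
    derivatives.  Constant input columns are fitted with that dimension's
    lengthscale pinned at its upper bound (the column carries no signal).
    Deterministic given ``seed``.
    """
    ci = smoothed.gene_index(model.child)
    genes = [model.child] + list(model.parents)
    X = np.column_stack([smoothed.values[smoothed.gene_index(g)] for g in genes])
    y = smoothed.derivatives[ci].astype(float)
    y_mean = float(y.mean())
    yc = y - y_mean
    target_sd = max(float(np.std(yc)), 1e-10)

    col_sd = X.std(axis=0)
    degenerate = col_sd < 1e-12
    scale = np.where(degenerate, 1.0, col_sd)
    Xs = (X - X.mean(axis=0)) / scale

    p = X.shape[1]
    sb = (1e-4 * target_sd, 1e2 * target_sd)
    log_bounds = [tuple(np.log(ARD_LENGTHSCALE_BOUNDS))] * p + [tuple(np.log(sb))] * 2
    for j in np.where(degenerate)[0]:
        top = np.log(ARD_LENGTHSCALE_BOUNDS[1])
        log_bounds[j] = (top, top)  # pinned: constant column carries no signal

    def unpack(theta):
        v = np.exp(theta)
        return v[:p], v[p], v[p + 1]

    def neg_lml(theta):
        ls, sf, sn = unpack(theta)
        try:
            return -ard_log_marginal_likelihood(yc, Xs, ls, sf, sn)
        except (GPFitError, np.linalg.LinAlgError):
            return 1e12

    rng = np.random.default_rng(seed)
    informed = [0.0] * p + [np.log(target_sd), np.log(0.1 * target_sd)]
    for j in np.where(degenerate)[0]:
        informed[j] = np.log(ARD_LENGTHSCALE_BOUNDS[1])
    starts = [np.array(informed)]
    for _ in range(max(restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in log_bounds]))

    best = None
    for x0 in starts:
        res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=log_bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e12:
        raise GPFitError(f"non-parametric fit failed for child {model.child}")
    ls, sf, sn = unpack(best.x)
    return NonparametricFit(
        model=model,
        lengthscales=ls,
        signal_sd=float(sf),
        noise_sd=float(sn),
        max_log_likelihood=-float(best.fun),
    )


def fit_all_nonparametric(
    child: int,
    candidates: Sequence[CandidateModel],
    smoothed: SmoothedTrajectories,
    restarts: int = 5,
    seed: int = 0,
) -> list:
    """Fit every untyped candidate of one child; order preserved, failures isolated."""
    if any(m.child != child for m in candidates):
        raise ValueError("all candidates must share the child gene")
    if any(m.typed for m in candidates):
        raise ValueError("non-parametric candidates must be untyped")
    fits = []
    for m in candidates:
        mseed = (seed * 1_000_003 + zlib.crc32(m.to_json().encode())) % 2**31
        try:
            fits.append(fit_nonparametric(m, smoothed, restarts=restarts, seed=mseed))
        except GPFitError:
            fits.append(
                NonparametricFit(
                    model=m,
                    lengthscales=np.full(m.n_parents + 1, np.nan),
                    signal_sd=np.nan,
                    noise_sd=np.nan,
                    max_log_likelihood=-np.inf,
                )
            )
    return fits
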
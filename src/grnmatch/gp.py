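"""Gaussian-process smoothing of expression time courses and their derivatives.

Single-output GPs use a squared-exponential kernel
``k(t, t') = sigma_f^2 exp(-(t - t')^2 / (2 l^2))`` with a zero-mean prior
applied after centring each gene's series.  Hyperparameters
``(sigma_f, sigma_n, l)`` are found by maximising the log marginal likelihood

    ln p(x | t) = -1/2 x^T (K + sigma_n^2 I)^-1 x
                  - 1/2 ln |K + sigma_n^2 I| - D/2 ln 2 pi

over a log-parameterised, bounded space with seeded multi-starts.  The
posterior mean derivative is available in closed form: the cross-covariance
between the derivative process and the observations is
``[L*]_ij = (t_i - t*_j) / l^2 * [K*]_ij``, so
``dx*/dt = L*^T-contracted (K + sigma_n^2 I)^-1 x``.

Multi-output smoothing uses intrinsic coregionalisation: the joint kernel
over all N genes is ``B (x) k`` (Kronecker product) with a positive
semi-definite coregionalisation matrix B (signal variances folded into its
diagonal) and a single shared lengthscale.  The likelihood and predictions
exploit the Kronecker eigenstructure, so each evaluation costs
O(N^3 + D^3 + N^2 D^2) instead of O((ND)^3).  Multi-output derivatives are
taken by forward differences with step delta = 1e-4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.optimize import minimize

__all__ = [
    "GPHyperparameters",
    "GPFitResult",
    "CoregionalisedGPFit",
    "SmoothedTrajectories",
    "se_kernel",
    "log_marginal_likelihood",
    "fit_gp",
    "posterior_mean_and_cov",
    "posterior_derivative",
    "fit_multioutput_gp",
    "multioutput_posterior_mean",
    "numeric_derivative",
    "smooth_dataset",
]

#: Relative diagonal jitter added before Cholesky factorisation.
JITTER = 1e-8

#: Forward-difference step (time units) for multi-output derivatives.
DERIVATIVE_DELTA = 1e-4

#: Bounds for the lengthscale (time units) during optimisation.
LENGTHSCALE_BOUNDS = (1e-2, 1e3)

#: Bounds for sigma_f and sigma_n as multiples of the data standard deviation.
SIGMA_BOUND_FACTORS = (1e-4, 1e2)


class GPFitError(RuntimeError):
    """Raised when every hyperparameter optimisation start fails."""


@dataclass(frozen=True)
class GPHyperparameters:
    signal_sd: float
    noise_sd: float
    lengthscale: float

    def __post_init__(self) -> None:
        if min(self.signal_sd, self.noise_sd, self.lengthscale) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class GPFitResult:
    """A fitted single-output GP: hyperparameters plus centred training data."""

    hyper: GPHyperparameters
    train_times: np.ndarray
    train_values: np.ndarray  # centred
    train_mean: float
    log_marginal_likelihood: float


@dataclass
class CoregionalisedGPFit:
    """A fitted intrinsic-coregionalisation multi-output GP.

    ``coreg_matrix`` (B) is symmetric PSD; the base kernel has unit signal
    variance (amplitudes live on B's diagonal) with one shared lengthscale.
    """

    coreg_matrix: np.ndarray
    lengthscale: float
    noise_sd: float
    train_times: np.ndarray
    train_values: np.ndarray  # N x D, centred per gene
    train_means: np.ndarray  # per-gene offsets
    log_marginal_likelihood: float

    @property
    def n_outputs(self) -> int:
        return self.coreg_matrix.shape[0]


@dataclass
class SmoothedTrajectories:
    """GP-smoothed expression values and derivatives at S prediction points."""

    pred_times: np.ndarray
    values: np.ndarray  # N x S
    derivatives: np.ndarray  # N x S
    gene_names: list
    source: str  # "single_output" | "multi_output"

    def __post_init__(self) -> None:
        self.pred_times = np.asarray(self.pred_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.derivatives = np.asarray(self.derivatives, dtype=float)
        if self.values.shape != self.derivatives.shape:
            raise ValueError("values and derivatives must share a shape")
        if not np.all(np.isfinite(self.derivatives)):
            raise ValueError("derivatives must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene: int) -> int:
        if not 0 <= gene < self.n_genes:
            raise KeyError(f"gene {gene} not in smoothed data")
        return gene

    def to_csv(self, path: Union[str, Path]) -> None:
        df = pd.DataFrame({"time": self.pred_times})
        for i, name in enumerate(self.gene_names):
            df[name] = self.values[i]
        for i, name in enumerate(self.gene_names):
            df[f"d{name}"] = self.derivatives[i]
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: Union[str, Path], source: str = "single_output") -> "SmoothedTrajectories":
        df = pd.read_csv(path)
        names = [c for c in df.columns[1:] if not c.startswith("d")]
        return cls(
            pred_times=df["time"].to_numpy(),
            values=df[names].to_numpy().T,
            derivatives=df[[f"d{n}" for n in names]].to_numpy().T,
            gene_names=names,
            source=source,
        )


# --------------------------------------------------------------------------
# Kernel and likelihood
# --------------------------------------------------------------------------

def se_kernel(t, t2, hyper: GPHyperparameters) -> np.ndarray:
    """Squared-exponential covariance; broadcasts over array inputs."""
    t = np.asarray(t, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    d = t[..., None] - t2[None, ...] if t.ndim == 1 and t2.ndim == 1 else t - t2
    return hyper.signal_sd**2 * np.exp(-(d**2) / (2.0 * hyper.lengthscale**2))


def _noisy_kernel_cholesky(times: np.ndarray, hyper: GPHyperparameters):
    k = se_kernel(times, times, hyper)
    k[np.diag_indices_from(k)] += hyper.noise_sd**2 + JITTER * hyper.signal_sd**2
    try:
        return cho_factor(k, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - jitter guards this
        raise GPFitError(f"kernel matrix not PSD (l={hyper.lengthscale:g})") from exc


def log_marginal_likelihood(values, times, hyper: GPHyperparameters) -> float:
    """Log marginal likelihood of observed values under the GP (zero mean)."""
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.shape != t.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("values and times must be equal-length vectors")
    cf = _noisy_kernel_cholesky(t, hyper)
    alpha = cho_solve(cf, x)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * x @ alpha - 0.5 * logdet - 0.5 * len(x) * np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# Single-output fitting and prediction
# --------------------------------------------------------------------------

def _sigma_bounds(data_sd: float):
    sd = max(data_sd, 1e-8)
    return (SIGMA_BOUND_FACTORS[0] * sd, SIGMA_BOUND_FACTORS[1] * sd)


def fit_gp(
    values,
    times,
    restarts: int = 5,
    seed: int = 0,
    fixed_lengthscale: Optional[float] = None,
) -> GPFitResult:
    """Maximise the marginal likelihood over (sigma_f, sigma_n[, l]) in log space.

    The series is centred before fitting; the offset is restored on
    prediction (derivatives are unaffected).  Multi-starts are drawn
    log-uniformly within the bounds from a seeded generator; the best
    optimum is returned.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if fixed_lengthscale is None and len(t) < 3:
        raise ValueError("need at least 3 points to fit a free lengthscale")
    mean = float(np.mean(x))
    xc = x - mean
    data_sd = float(np.std(xc))
    sb = _sigma_bounds(data_sd)
    free_l = fixed_lengthscale is None

    def unpack(theta) -> GPHyperparameters:
        vals = np.exp(theta)
        l = vals[2] if free_l else fixed_lengthscale
        return GPHyperparameters(signal_sd=vals[0], noise_sd=vals[1], lengthscale=l)

    def neg_lml(theta):
        try:
            return -log_marginal_likelihood(xc, t, unpack(theta))
        except (GPFitError, np.linalg.LinAlgError):
            return 1e12

    log_bounds = [tuple(np.log(sb))] * 2
    if free_l:
        log_bounds.append(tuple(np.log(LENGTHSCALE_BOUNDS)))
    rng = np.random.default_rng(seed)
    span = t[-1] - t[0]
    head = [np.log(max(data_sd, 1e-8)), np.log(max(0.05 * data_sd, 1e-8))]
    starts = []
    if free_l:
        # the likelihood is multimodal in the lengthscale (smooth optima
        # compete with an "all noise" one), so walk a deterministic ladder of
        # lengthscale starts before random restarts
        spacing = float(np.median(np.diff(t)))
        ladder = np.geomspace(
            np.clip(spacing, *LENGTHSCALE_BOUNDS),
            np.clip(span / 2.0, *LENGTHSCALE_BOUNDS),
            num=4,
        )
        for l0 in ladder:
            starts.append(np.array(head + [np.log(l0)]))
    else:
        starts.append(np.array(head))
    for _ in range(max(restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in log_bounds]))

    best = None
    for x0 in starts:
        res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=log_bounds)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e12:
        raise GPFitError("all hyperparameter optimisation starts failed")
    hyper = unpack(best.x)
    return GPFitResult(
        hyper=hyper,
        train_times=t,
        train_values=xc,
        train_mean=mean,
        log_marginal_likelihood=-float(best.fun),
    )


def posterior_mean_and_cov(fit: GPFitResult, pred_times):
    """Posterior mean (offset restored) and covariance at ``pred_times``."""
    ts = np.asarray(pred_times, dtype=float)
    cf = _noisy_kernel_cholesky(fit.train_times, fit.hyper)
    kstar = se_kernel(fit.train_times, ts, fit.hyper)  # D x S
    alpha = cho_solve(cf, fit.train_values)
    mean = kstar.T @ alpha + fit.train_mean
    v = cho_solve(cf, kstar)
    cov = se_kernel(ts, ts, fit.hyper) - kstar.T @ v
    return mean, cov


def posterior_derivative(fit: GPFitResult, pred_times) -> np.ndarray:
    """Analytic posterior mean derivative of the GP at ``pred_times``."""
    ts = np.asarray(pred_times, dtype=float)
    cf = _noisy_kernel_cholesky(fit.train_times, fit.hyper)
    kstar = se_kernel(fit.train_times, ts, fit.hyper)  # D x S
    lstar = ((fit.train_times[:, None] - ts[None, :]) / fit.hyper.lengthscale**2) * kstar
    alpha = cho_solve(cf, fit.train_values)
    return lstar.T @ alpha


# --------------------------------------------------------------------------
# Multi-output (intrinsic coregionalisation)
# --------------------------------------------------------------------------

def _icm_lml(Y: np.ndarray, times: np.ndarray, B: np.ndarray, l: float, sn: float) -> float:
    """Marginal likelihood of stacked outputs under K = B (x) k + sn^2 I.

    Uses the eigendecompositions of B (N x N) and of the unit-variance time
    kernel (D x D): the joint eigenvalues are the Kronecker products.
    """
    n, d = Y.shape
    kt = np.exp(-((times[:, None] - times[None, :]) ** 2) / (2.0 * l**2))
    kt[np.diag_indices_from(kt)] += JITTER
    wb, ub = eigh(B)
    wt, ut = eigh(kt)
    wb = np.maximum(wb, 0.0)
    wt = np.maximum(wt, 0.0)
    lam = np.outer(wb, wt) + sn**2  # N x D joint eigenvalues
    ytil = ub.T @ Y @ ut
    quad = np.sum(ytil**2 / lam)
    logdet = np.sum(np.log(lam))
    return float(-0.5 * quad - 0.5 * logdet - 0.5 * n * d * np.log(2.0 * np.pi))


def _tril_indices(n: int):
    return np.tril_indices(n)


def _pack_B(L: np.ndarray, n: int) -> np.ndarray:
    """Parameter vector from a lower Cholesky factor (log on the diagonal)."""
    theta = L[_tril_indices(n)].copy()
    diag_pos = np.cumsum(np.arange(1, n + 1)) - 1
    theta[diag_pos] = np.log(L[np.diag_indices(n)])
    return theta


def _unpack_B(theta: np.ndarray, n: int) -> np.ndarray:
    L = np.zeros((n, n))
    L[_tril_indices(n)] = theta
    diag_pos = np.cumsum(np.arange(1, n + 1)) - 1
    L[np.diag_indices(n)] = np.exp(theta[diag_pos])
    return L @ L.T


def fit_multioutput_gp(
    values: np.ndarray,
    times,
    restarts: int = 5,
    seed: int = 0,
    fixed_lengthscale: Optional[float] = None,
) -> CoregionalisedGPFit:
    """Fit an intrinsic-coregionalisation GP to an N x D expression matrix.

    The coregionalisation matrix B is parameterised by its Cholesky factor
    (full rank, log-diagonal); signal variances are folded into B's diagonal
    and a single lengthscale is shared across outputs.
    """
    Y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    n, d = Y.shape
    if n < 2:
        raise ValueError("multi-output fit needs at least 2 genes")
    means = Y.mean(axis=1)
    Yc = Y - means[:, None]
    data_sd = float(np.std(Yc))
    sb = _sigma_bounds(data_sd)
    free_l = fixed_lengthscale is None
    ntri = n * (n + 1) // 2
    span = t[-1] - t[0]
    # A lengthscale below the sampling interval lets the joint likelihood
    # collapse onto a near-diagonal kernel that interpolates the training
    # grid but is meaningless between points; floor it at half the median
    # spacing.
    l_bounds = (
        max(LENGTHSCALE_BOUNDS[0], 0.5 * float(np.median(np.diff(t)))),
        LENGTHSCALE_BOUNDS[1],
    )

    def unpack(theta):
        B = _unpack_B(theta[:ntri], n)
        sn = np.exp(theta[ntri])
        l = np.exp(theta[ntri + 1]) if free_l else fixed_lengthscale
        return B, l, sn

    def neg_lml(theta):
        B, l, sn = unpack(theta)
        try:
            return -_icm_lml(Yc, t, B, l, sn)
        except np.linalg.LinAlgError:  # pragma: no cover
            return 1e12

    # bounds: off-diagonal Cholesky entries box-bounded by the data scale,
    # log-diagonal and log-(sigma_n, l) within the usual factors
    bounds = []
    diag_pos = set((np.cumsum(np.arange(1, n + 1)) - 1).tolist())
    for i in range(ntri):
        if i in diag_pos:
            bounds.append(tuple(np.log(sb)))
        else:
            bounds.append((-10.0 * max(data_sd, 1e-8), 10.0 * max(data_sd, 1e-8)))
    bounds.append(tuple(np.log(sb)))
    if free_l:
        bounds.append(tuple(np.log(l_bounds)))

    rng = np.random.default_rng(seed)
    gene_sd = np.maximum(Yc.std(axis=1), 1e-8)
    L0 = np.diag(gene_sd)
    head = list(_pack_B(L0, n)) + [np.log(max(0.1 * data_sd, 1e-8))]
    starts = []
    if free_l:
        # the likelihood is multimodal in the shared lengthscale (smooth
        # near-interpolating optima compete with an "all noise" one), so walk
        # a deterministic ladder of lengthscale starts before random restarts
        ladder = np.geomspace(l_bounds[0] * 1.05, min(span, l_bounds[1]), num=4)
        for l0 in ladder:
            starts.append(np.array(head + [np.log(l0)]))
    else:
        starts.append(np.array(head))
    for _ in range(max(restarts - 1, 0)):
        jit = np.array(starts[0])
        # perturb the diagonal/sigma/lengthscale entries; keep off-diagonals small
        for i, (lo, hi) in enumerate(bounds):
            if i in diag_pos or i >= ntri:
                jit[i] = rng.uniform(max(lo, jit[i] - 2.0), min(hi, jit[i] + 2.0))
            else:
                jit[i] = rng.normal(0.0, 0.1 * max(data_sd, 1e-8))
        starts.append(jit)

    best = None
    for x0 in starts:
        res = minimize(neg_lml, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 300})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e12:
        raise GPFitError("all multi-output optimisation starts failed")
    B, l, sn = unpack(best.x)
    return CoregionalisedGPFit(
        coreg_matrix=B,
        lengthscale=l,
        noise_sd=sn,
        train_times=t,
        train_values=Yc,
        train_means=means,
        log_marginal_likelihood=-float(best.fun),
    )


def multioutput_posterior_mean(fit: CoregionalisedGPFit, pred_times) -> np.ndarray:
    """Posterior mean of every output at ``pred_times`` (N x S, offsets restored)."""
    ts = np.asarray(pred_times, dtype=float)
    t = fit.train_times
    n, d = fit.train_values.shape
    kt = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * fit.lengthscale**2))
    kt[np.diag_indices_from(kt)] += JITTER
    wb, ub = eigh(fit.coreg_matrix)
    wt, ut = eigh(kt)
    lam = np.outer(np.maximum(wb, 0.0), np.maximum(wt, 0.0)) + fit.noise_sd**2
    ytil = ub.T @ fit.train_values @ ut
    Z = ub @ (ytil / lam) @ ut.T  # (B (x) kt + sn^2 I)^-1 y, unstacked N x D
    kstar = np.exp(-((t[:, None] - ts[None, :]) ** 2) / (2.0 * fit.lengthscale**2))
    return fit.coreg_matrix @ Z @ kstar + fit.train_means[:, None]


def numeric_derivative(predict: Callable, pred_times, delta: float = DERIVATIVE_DELTA) -> np.ndarray:
    """Forward-difference derivative (x(t + delta) - x(t)) / delta."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    ts = np.asarray(pred_times, dtype=float)
    return (np.asarray(predict(ts + delta)) - np.asarray(predict(ts))) / delta


# --------------------------------------------------------------------------
# Dataset-level smoothing
# --------------------------------------------------------------------------

def smooth_dataset(
    data,
    mode: str = "single_output",
    n_pred: int = 21,
    restarts: int = 5,
    seed: int = 0,
    fixed_lengthscale: Optional[float] = None,
) -> SmoothedTrajectories:
    """Smooth every gene of an ExpressionDataset and evaluate derivatives.

    ``n_pred`` evenly spaced prediction points span the observation window.
    Single-output mode fits one GP per gene and uses the analytic derivative;
    multi-output mode fits one coregionalised GP and differentiates its mean
    numerically (forward differences, delta = 1e-4).
    """
    if n_pred < 2:
        raise ValueError("n_pred must be >= 2")
    ts = np.linspace(data.times[0], data.times[-1], n_pred)
    n = data.n_genes
    values = np.empty((n, n_pred))
    derivs = np.empty((n, n_pred))
    if mode == "single_output":
        for g in range(n):
            fit = fit_gp(
                data.values[g], data.times,
                restarts=restarts, seed=seed + 1000 * g,
                fixed_lengthscale=fixed_lengthscale,
            )
            values[g], _ = posterior_mean_and_cov(fit, ts)
            derivs[g] = posterior_derivative(fit, ts)
    elif mode == "multi_output":
        fit = fit_multioutput_gp(
            data.values, data.times,
            restarts=restarts, seed=seed,
            fixed_lengthscale=fixed_lengthscale,
        )
        values[:] = multioutput_posterior_mean(fit, ts)
        derivs[:] = numeric_derivative(
            lambda tq: multioutput_posterior_mean(fit, tq), ts
        )
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    return SmoothedTrajectories(
        pred_times=ts, values=values, derivatives=derivs,
        gene_names=list(data.gene_names), source=mode,
    )
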
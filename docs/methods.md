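# Methods

## Overview

`grnmatch` infers gene regulatory networks (GRNs) from expression time
courses by two-step gradient matching. Step one interpolates the data with
Gaussian processes (GPs) and extracts trajectory derivatives; step two
scores candidate regulatory models per gene by how well a model's predicted
rate of change matches those derivatives, without ever integrating the ODE
system. Candidate scores are converted to BIC-based Schwarz weights and
averaged into per-edge confidences, which are evaluated against the known
network with precision–recall curves (AUPR).

Because gradient matching treats each gene's rate equation conditionally on
its candidate parents, the model space factorises per child gene:
`N · Σ_{i=0..M} C(N−1, i) · F^i` candidate models for `N` genes, `F`
interaction types and in-degree cap `M` (405 for `N=5, F=2` uncapped, 165
with `M=2`, 55 untyped), versus ~3.5·10⁹ fully coupled 5-gene systems.

## Dynamical model

Each gene's mRNA concentration follows

    dx_n/dt = s_n + β_n · f_n(x_parents) − γ_n · x_n

with basal transcription rate `s_n` (concentration/time), regulation
strength `β_n` (concentration/time), first-order decay `γ_n` (1/time), and a
regulation function `f_n` built from Hill terms: activation
`x^h/(k^h + x^h)`, repression `k^h/(k^h + x^h)` with threshold `k`
(concentration) and coefficient `h` (dimensionless, ≥ 1).

**Multi-parent composition.** `f_n` is the *arithmetic mean* of the
per-parent Hill terms. This keeps `f_n ∈ [0, 1]` for any in-degree, so `β_n`
retains its meaning as the maximum regulatory production rate. The same
composition is used by the simulator and by parametric inference, making the
two self-consistent; multiplicative (AND-gate) composition is a plausible
alternative that this package does not implement.

## Synthetic benchmarks

Default kinetics for all benchmark networks: `s = 0.05`, `β = 1.0`,
`γ = 0.3`, `k = 1.0`, `h = 2` on `t ∈ [0, 100]` — chosen once to give
non-trivial dynamics (steady-state levels ≈ 0.2–3.5, relaxation timescale
1/γ ≈ 3.3 time units).

- **`non_oscillatory_5`** — 5 genes, 8 typed interactions: a three-gene
  repressor ring driving two downstream reporters, plus one extra repression
  (0 ⊣ 2) that closes a double-negative loop and destroys the ring's limit
  cycle. Trajectories relax to a fixed point after an initial transient.
- **`oscillatory_5`** — the same network with the extra edge removed
  (7 interactions) and `h = 4` on the repressor ring, which sustains a limit
  cycle (verified: every gene shows ≥ 2 interior local maxima on the default
  horizon).
- **`stochastic_10`** — 10 genes, 10 typed interactions drawn reproducibly
  from a seed; simulated with Euler–Maruyama (2000 steps), multiplicative
  `0.1·√x` process noise reflected at zero, plus i.i.d. Gaussian
  observation noise (sd 0.05) truncated at zero, observed at 20 time points.

**What the generator does not emulate.** Real expression data involve
mRNA/protein layers, transcriptional bursting, cell-population averaging and
non-Gaussian measurement error; the stochastic benchmark reproduces only the
statistical character (process + observation noise) of such data. Passing
benchmarks therefore demonstrates correctness and qualitative behaviour of
the inference machinery, not performance on any real organism's data.

Deterministic observation grids default to 21 or 41 evenly spaced points;
the stochastic benchmark uses 20. Deterministic ODE integration uses LSODA
with `rtol = 1e-10`.

## GP smoothing

Single-output GPs use the squared-exponential kernel
`k(t,t') = σ_f² exp(−(t−t')²/2l²)` with a zero-mean prior after subtracting
each gene's training mean (restored on prediction; derivatives unaffected).
Hyperparameters `(σ_f, σ_n, l)` maximise the log marginal likelihood over a
log-parameterised bounded space: `l ∈ [10⁻², 10³]` time units, both σ's in
`[10⁻⁴, 10²]` × data sd. The posterior mean derivative is analytic:
`dx*/dt = L*ᵀ(K+σ_n²I)⁻¹x` with `[L*]_ij = ((t_i−t*_j)/l²)[K*]_ij`.

Multi-output smoothing uses intrinsic coregionalisation: joint kernel
`B ⊗ k` over all `N` genes, with a full-rank PSD matrix `B` (Cholesky
parameterised; per-gene signal variances folded into its diagonal) and a
single shared lengthscale. Likelihood and predictions use the Kronecker
eigendecomposition, costing `O(N³ + D³ + N²D²)` per evaluation. Derivatives
of the multi-output mean are forward differences with step `δ = 10⁻⁴` time
units (a compromise between truncation error and noise amplification).

Numerical choices:

- diagonal jitter `10⁻⁸·σ_f²` before every Cholesky factorisation;
- the marginal likelihood is multimodal in `l` (smooth near-interpolating
  optima compete with an "explain everything as noise" optimum), so
  optimisation starts from a deterministic ladder of lengthscales between
  the sampling interval and half the span, followed by seeded random
  restarts;
- the multi-output lengthscale is additionally floored at half the median
  sampling interval: below that, the joint likelihood can collapse onto a
  near-diagonal kernel that interpolates the training grid exactly but is
  meaningless — and derivative-hostile — between grid points.

## Parametric gradient matching

For each typed candidate model the rate law is fitted by minimising the L2
distance `Σ_i (f(x̂(t_i), α) − dx̂_n/dt(t_i))²` over all `S` prediction
points, with bounded L-BFGS-B from seeded log-uniform multi-starts (restart
seeds derive from a stable hash of the model identity, so results are
independent of candidate ordering).

Two prior regimes:

- **without prior** — wide boxes: `s, β ∈ [0, 10]`, `γ ∈ [10⁻³, 10]`,
  `k ∈ [10⁻², 10²·max(x̂)]`, `h ∈ [1, 4]`;
- **with prior** — `s_n, γ_n` fixed to the generating model's values, and
  `[0.5·ref, 2·ref]` boxes around the reference kinetics for `β`, `k`, `h`.

The Hill coefficient is optimised continuously to keep the objective
smooth. The free-parameter count entering the BIC is `G = 3 + 2·|parents|`
without prior and `1 + 2·|parents|` with prior; for the empty-parent model
`β` remains in the optimised vector even though it multiplies a vanished
regulation term, so the stated count holds uniformly (the inert dimension
only adds a constant `ln S` to that model's penalty).

## Non-parametric gradient matching

Each gene's smoothed derivative is regressed on the smoothed expression of
its candidate parents *and always of itself* (decay makes self-dependence
ubiquitous; the forced self-input is a flag and does not change the size of
the candidate space). The kernel is a squared exponential over the input
(expression) space with one automatic-relevance-determination (ARD)
lengthscale per input gene — the inputs are expression levels rather than
time, and ARD lets the likelihood shrink away irrelevant parents. Inputs
are standardised per dimension, targets centred; constant input columns get
their lengthscale pinned at the upper bound. The hyperparameter count is
`G = (|parents| + 1) + 2`.

## Scoring and evaluation

- Parametric BIC: `ln(S)·G + S·ln(dist_L2/S)`, with zero distances floored
  at `10⁻³⁰⁰` so a perfect fit dominates the weighting instead of producing
  NaNs. Non-parametric BIC: `ln(S)·G − 2·ln L_max`.
- Schwarz weights `exp(−Δ_i/2)/Σ_j exp(−Δ_j/2)` are computed min-shifted;
  infinite BICs (failed fits) get weight zero.
- Edge weights sum the Schwarz weights of every model of the child that
  contains the edge. Directed weights marginalise the two interaction
  types. Undirected weights combine the two directions by **noisy-OR**,
  `1 − (1−w_ab)(1−w_ba)`: the two directed weights come from different
  children's model sets, so they are not mutually exclusive and a raw sum
  could exceed 1. Self-interactions never enter edge tables.
- AUPR is step-wise average precision with tied-weight groups admitted
  jointly — this avoids the optimism of linear interpolation in PR space.
  The random baseline is the true-edge prevalence |truth|/|candidates|.
  Note that the *expected* average precision of a finite random ranking
  exceeds the prevalence by a positive finite-size term (≈ +0.08 on the
  5-gene directed domain, ≈ +0.014 on a 20-gene domain with 10 true
  edges); the prevalence baseline is the standard convention and the bias
  vanishes in the sparse large-network regime the AUPR is intended for.

## Benchmark protocol and problem sizes

`run_experiment` executes one settings cell for `n_repeats` repeats.
Deterministic datasets are simulated once and shared across repeats
(repeats vary optimiser seeds only); stochastic datasets are resimulated
with a fresh seed per repeat. The shipped acceptance script pools each
method's mean AUPR over a noise-free settings grid — both 5-gene variants ×
both interpolation modes at 41 prediction points, `M = 2`, one repeat,
three optimiser restarts per fit — and runs the stochastic 10-gene
benchmark at 21 prediction points; these sizes keep a full end-to-end run
in the minutes range on a single CPU while exercising every code path.

## Known limitations

- **Boundary derivative bias.** A GP smoother sees data on only one side of
  the window edges, so derivative estimates at the first/last points are
  biased whenever an initial transient is faster than the sampling
  interval. The non-parametric method is most sensitive to this: on the
  damped 5-gene benchmark with single-output smoothing its directed-aim
  AUPR hovers at the random baseline (≈ 0.38 vs 0.40), while the same
  method on oscillatory data (0.70) or with multi-output smoothing (0.63)
  is clearly above baseline. Parametric methods, whose rate laws constrain
  the fit globally, are more robust.
- Intrinsic coregionalisation shares one lengthscale across genes and
  cannot represent phase lags between them (its cross-covariances are
  symmetric in time), limiting interpolation gains on strongly delayed
  oscillations.
- "With prior" uses the generating model's own rates as its reference — a
  best-case operationalisation of known kinetics.
- The L2 objective weights all prediction points equally and ignores the
  GP's posterior uncertainty; adaptive gradient-matching schemes that feed
  the ODE back into the GP fit are out of scope.
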
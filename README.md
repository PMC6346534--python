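# grnmatch

Gene regulatory network (GRN) inference from expression time courses by
**Gaussian-process gradient matching** with BIC model averaging.

Reverse-engineering a GRN from time-resolved mRNA measurements by fitting
coupled nonlinear ODEs is expensive: every candidate topology would have to
be integrated numerically, and the number of candidate topologies explodes
with network size. Gradient matching sidesteps the integration: a Gaussian
process (GP) is fitted to each gene's time course, the trajectory
derivative dx̂/dt is obtained in closed form from the GP, and each candidate
regulatory model is scored by how closely its right-hand side matches that
derivative. Because each gene's equation

    dx_n/dt = s_n + β_n · f_n(x_parents; k, h) − γ_n · x_n

(with Hill-kinetics regulation f_n) is matched independently given its
candidate parents, the model space shrinks from
(Σᵢ C(N−1,i)·Fⁱ)^N fully coupled systems to N·Σ_{i≤M} C(N−1,i)·Fⁱ
decoupled candidates — 405 instead of 3.5·10⁹ for a 5-gene network with
two interaction types, or 165 with an in-degree cap M = 2.

The package implements, end to end:

- **Simulators** for benchmark data: deterministic 5-gene Hill-kinetics
  networks (a damped 8-interaction variant and an oscillatory 7-interaction
  variant) and a stochastic 10-gene network with process and observation
  noise.
- **GP smoothing**: independent single-output GPs (squared-exponential
  kernel, analytic derivatives) and a multi-output GP with intrinsic
  coregionalisation (kernel B ⊗ k, shared lengthscale, numerical
  derivatives with δ = 10⁻⁴).
- **Three inference methods**: parametric ODE gradient matching with and
  without prior kinetic knowledge (L2 distance, Eq.-style
  `Σᵢ (f(x̂(tᵢ),α) − dx̂/dtᵢ)²`), and a non-parametric method that models
  each derivative as an ARD-GP function of candidate parent expressions.
- **Model averaging**: BIC per candidate (`ln(S)·G + S·ln(dist/S)`
  parametric, `ln(S)·G − 2·ln L̂` non-parametric), Schwarz weights
  `exp(−ΔBIC/2)` normalised per child gene, and per-edge confidences by
  summing the weights of all models containing the edge.
- **Evaluation**: precision–recall curves and AUPR for typed (T), directed
  (D) and undirected (U) inference aims, with the prevalence random
  baseline.

See `docs/methods.md` for the full model description, numerical choices and
known limitations.

## Worked example

Run the full pipeline on the deterministic 5-gene benchmark from the shell:

```sh
grnmatch simulate non_oscillatory_5 --n-points 41 --out expr.csv --truth-out truth.tsv
grnmatch smooth expr.csv --n-pred 41 --out smoothed.csv
grnmatch infer smoothed.csv --method ode_without_prior --max-parents 2 --out fits.jsonl
grnmatch score fits.jsonl --aim directed --n-pred 41 --out weights.tsv
grnmatch evaluate weights.tsv truth.tsv --aim directed
```

which prints

```
AUPR (directed): 0.5935  baseline: 0.4000
```

— the BIC-averaged edge ranking recovers the directed network far above the
random baseline of 8 true edges / 20 candidate pairs = 0.40. The same flow
is available from Python:

```python
from grnmatch import ExperimentConfig, run_experiment

cfg = ExperimentConfig(inference_method="ode_with_prior",
                       dataset_variant="non_oscillatory_5",
                       n_pred_points=41, max_parents=2,
                       n_repeats=1, base_seed=1, restarts=3,
                       aims=("typed", "directed", "undirected"))
print(run_experiment(cfg).per_aim_aupr)
# {'typed': 1.0, 'directed': 1.0, 'undirected': 1.0}
```

With known basal/decay rates and constrained parameter ranges
("with prior"), the parametric method recovers the full typed network
perfectly on noise-free data; without the prior, typed performance drops to
0.779 under the same settings — interaction *types* are only reliably
recoverable with kinetic prior knowledge.

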
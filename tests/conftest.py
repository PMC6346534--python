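"""Shared fixtures: small simulated datasets and cached GP smoothings."""

import numpy as np
import pytest

from grnmatch import (
    GeneKinetics,
    InteractionType,
    ODEModelSpec,
    make_benchmark_spec,
    simulate_deterministic,
)
from grnmatch.gp import SmoothedTrajectories, smooth_dataset

ACT = InteractionType.ACTIVATION
REP = InteractionType.REPRESSION


def decay_gene(basal=0.0, decay=0.3):
    return GeneKinetics(basal_rate=basal, sensitivity=0.0, decay_rate=decay)


@pytest.fixture(scope="session")
def two_gene_activation_spec():
    """Gene 0 decays from a high start; gene 1 is activated by gene 0."""
    kin = (
        GeneKinetics(basal_rate=0.05, sensitivity=0.0, decay_rate=0.15),
        GeneKinetics(
            basal_rate=0.05, sensitivity=1.0, decay_rate=0.3,
            parents=(0,), itypes=(ACT,), hill_thresholds=(1.0,), hill_coefficients=(2.0,),
        ),
    )
    return ODEModelSpec(kinetics=kin, initial_state=np.array([2.0, 0.1]))


@pytest.fixture(scope="session")
def two_gene_smoothed(two_gene_activation_spec):
    """Noise-free 2-gene activation motif, smoothed at 21 points."""
    times = np.linspace(0.0, 30.0, 21)
    data = simulate_deterministic(two_gene_activation_spec, times)
    return smooth_dataset(data, mode="single_output", n_pred=21, restarts=5, seed=7)


@pytest.fixture(scope="session")
def oscillatory_dataset():
    spec, truth = make_benchmark_spec("oscillatory_5")
    times = np.linspace(0.0, 100.0, 21)
    data = simulate_deterministic(spec, times)
    data.truth = truth
    return data


@pytest.fixture(scope="session")
def exact_smoothed_trajectories():
    """Smoothed-trajectory container holding exact values and derivatives."""
    from grnmatch.simulate import ode_rhs

    spec, truth = make_benchmark_spec("non_oscillatory_5")
    ts = np.linspace(0.0, 100.0, 21)
    data = simulate_deterministic(spec, ts)
    d = np.array([ode_rhs(data.values[:, i], spec) for i in range(len(ts))]).T
    return SmoothedTrajectories(
        pred_times=ts,
        values=data.values,
        derivatives=d,
        gene_names=data.gene_names,
        source="single_output",
    ), truth
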
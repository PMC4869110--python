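"""Shared fixtures: small PWMs, toy genomes, and one mid-size simulated
experiment reused by the footprint/profile tests."""

import numpy as np
import pytest

from nucfoot.footprint import build_count_windows, fit_footprint_model
from nucfoot.motif_scan import Pwm
from nucfoot.simulate import SimConfig, make_informative_pwm, simulate_dataset


@pytest.fixture(scope="session")
def simple_pwm() -> Pwm:
    """7-position near-deterministic motif (consensus ACGTACG)."""
    counts = np.zeros((7, 4))
    for i, b in enumerate([0, 1, 2, 3, 0, 1, 2]):
        counts[i, b] = 100.0
    return Pwm.from_counts(counts, name="toy", pseudocount=0.5)


@pytest.fixture(scope="session")
def uniform_pwm() -> Pwm:
    return Pwm(np.full((6, 4), 0.25), name="uniform")


@pytest.fixture(scope="session")
def sim_small():
    """Light synthetic experiment for unit-level checks.

    n=600 sites at 120 reads/site is the smallest scale at which the
    mixture reliably resolves both components; the per-bp footprint profile
    needs enough pooled depth to rise above its own estimation noise.
    """
    cfg = SimConfig(n_sites=600, mean_reads=120.0, seed=5)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_small_fit(sim_small):
    windows = build_count_windows(sim_small.instances, sim_small.midpoints,
                                  sim_small.chrom_lengths)
    model, pi = fit_footprint_model(windows)
    return sim_small, windows, model, pi


@pytest.fixture()
def rng():
    """Fresh deterministic generator per test: results never depend on
    which other tests ran first."""
    return np.random.default_rng(123)
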
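import dataclasses

import numpy as np
import pytest

from peakdiff.simulate import SimulationConfig, scenario_presets, simulate_experiment


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small two-condition experiment cheap enough to emit as SAM files."""
    return SimulationConfig(
        seed=11,
        chromosomes={"chr1": 2_000_000, "chr2": 1_500_000},
        conditions=["A", "B"],
        replicates={"A": 2, "B": 2},
        n_shared_peaks=150,
        n_gained_peaks=100,
        gaining_condition="B",
        gained_basal_mean=3.0,
        fragments_per_sample=40_000,
        target_frip={"A": 0.08, "B": 0.20},
        nb_dispersion=0.02,
    )


@pytest.fixture(scope="session")
def emitted_experiment(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    sim = simulate_experiment(small_config, outdir)
    return sim, outdir


def nb_draw(rng, mu, alpha, size=None):
    """Gamma-Poisson NB sampler shared by test simulations."""
    lam = rng.gamma(1.0 / alpha, np.asarray(mu) * alpha, size=size)
    return rng.poisson(lam)
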
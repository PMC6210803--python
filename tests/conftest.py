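import numpy as np
import pytest

from kfgep.gep import GepConfig
from kfgep.synthetic import (
    SymbolSpec,
    default_forward_model,
    generate_dataset,
    linear_forward_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_gep_config():
    """A fast engine configuration for plumbing tests (not the study config)."""
    return GepConfig(population_size=30, n_generations=15, rng_seed=7)


@pytest.fixture(scope="session")
def linear_dataset():
    """Noiseless linear-observation world: 2 symbols, solvable exactly."""
    return generate_dataset(
        symbols=("fwd_slash", "arch"),
        trials_per_symbol=6,
        n_points=20,
        forward_model=linear_forward_model(noise_sd=0.0),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def nonlinear_dataset():
    """Small noisy nonlinear-world dataset for pipeline tests."""
    return generate_dataset(
        symbols=("fwd_slash", "arch", "circle"),
        trials_per_symbol=6,
        n_points=20,
        forward_model=default_forward_model(noise_sd=1.0),
        rng_seed=13,
    )


@pytest.fixture
def slash_spec():
    return SymbolSpec(symbol_id="fwd_slash", n_points=20, scale=100.0)
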
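import numpy as np
import pytest

from valvemir.synth import SynthConfig, simulate_expression, simulate_target_scores


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Full-size synthetic study at the emulated design (15 vs 16 arrays)."""
    return simulate_expression(default_config)


@pytest.fixture(scope="session")
def default_scores(default_config, default_dataset):
    _, _, _, truth = default_dataset
    return simulate_target_scores(default_config, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def small_config(**overrides) -> SynthConfig:
    """Scaled-down generator settings for fast unit tests."""
    base = dict(
        n_case=8,
        n_control=8,
        n_mirna=40,
        n_mrna=60,
        n_de_mirna=12,
        n_clusters=3,
        n_de_mrna=10,
        n_repressive_pairs=8,
        n_hub_targets=2,
        hub_parents=2,
        n_decoy_pairs=30,
        seed=0,
    )
    base.update(overrides)
    return SynthConfig(**base)
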
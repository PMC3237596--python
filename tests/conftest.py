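import pytest

from exonflow.simulate import SimulationConfig, simulate_experiment
from exonflow.summarize import quantile_normalize_matrix, summarize_chip


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale simulation config shared across module tests."""
    base = dict(
        n_genes=80,
        probesets_per_gene=(5, 7),
        probes_per_probeset=(4, 4),
        n_background_probes=800,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_experiment():
    return simulate_experiment(small_config())


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    return quantile_normalize_matrix(small_experiment.matrix)


@pytest.fixture(scope="session")
def small_estimates(small_experiment, small_normalized):
    return summarize_chip(small_normalized, small_experiment.annotation)
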
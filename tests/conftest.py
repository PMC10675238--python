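import numpy as np
import pytest

from fermsense import (
    BatchDataset,
    PipelineConfig,
    SwarmConfig,
    WeightedEnsembleSoftSensor,
    generate_dataset,
    split_by_batch,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset():
    """2 batches x 3 time points, 2 aux columns, 1 target."""
    return BatchDataset(
        batch_id=[1, 1, 1, 2, 2, 2],
        time_index=[0, 1, 2, 0, 1, 2],
        aux=np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0],
                      [1.5, 12.0], [2.5, 22.0], [3.5, 32.0]]),
        targets=np.array([[0.1], [0.2], [0.3], [0.15], [0.25], [0.35]]),
        aux_names=("a", "b"),
        target_names=("y",),
    )


@pytest.fixture(scope="session")
def benchmark_data():
    """The default synthetic benchmark: 15 batches x 60 points, 12/3 split."""
    ds = generate_dataset(seed=0)
    return split_by_batch(ds, 12)


@pytest.fixture(scope="session")
def small_config():
    """Cheap pipeline configuration for structural tests."""
    return PipelineConfig(swarm=SwarmConfig(population=8, max_iter=12))


@pytest.fixture(scope="session")
def fitted_small(benchmark_data, small_config):
    """One cheaply fitted ensemble, shared across structural tests."""
    train, _ = benchmark_data
    return WeightedEnsembleSoftSensor(train, "P", small_config).fit(seed=3)
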
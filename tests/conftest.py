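import numpy as np
import pytest

from adaptkit import case_study
from adaptkit.adapt_core import AdaptConfig
from adaptkit.interpolants import PhenotypeDataset
from adaptkit.synthetic_data import NoiseConfig, generate_snapshots


@pytest.fixture(scope="session")
def true_model():
    return case_study.build_true_system()


@pytest.fixture(scope="session")
def reduced_model():
    return case_study.build_reduced_model()


@pytest.fixture(scope="session")
def schedule():
    return case_study.intervention_schedule()


@pytest.fixture(scope="session")
def zero_noise_data(true_model, schedule):
    """Noise-free snapshot dataset plus its ground-truth record."""
    return generate_snapshots(true_model, schedule, NoiseConfig(max_rel_sd=0.0), rng=1)


@pytest.fixture(scope="session")
def noisy_data(true_model, schedule):
    """Snapshot dataset at 10% maximum relative noise (seeded)."""
    return generate_snapshots(true_model, schedule, NoiseConfig(max_rel_sd=0.1), rng=42)


@pytest.fixture
def small_config():
    return AdaptConfig(free_parameters=("k1",), nr=3, seed=7)


@pytest.fixture
def tiny_dataset():
    """Hand-written two-stage dataset for interpolant/IO unit tests."""
    return PhenotypeDataset(
        stage_times=np.array([0.0, 1.0]),
        observable_names=["A", "B"],
        means=np.array([[1.0, 2.0], [1.5, 1.0]]),
        sds=np.array([[0.1, 0.2], [0.1, 0.2]]),
    )
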
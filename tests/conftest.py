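import numpy as np
import pytest

from doughnose.synthetic import (
    ClassEffect,
    CycleSpec,
    SensorModel,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def cycle():
    return CycleSpec()


@pytest.fixture
def clean_model():
    """Noiseless, drift-free SnO2 sensor with fast response kinetics."""
    return SensorModel(
        sensor_id="S1",
        material="SnO2",
        baseline_ohm=50_000.0,
        tau_response_s=10.0,
        tau_recovery_s=60.0,
        noise_cv=0.0,
    )


@pytest.fixture
def pre_effect():
    return ClassEffect("W390", "PRE", 0.2, amplitude_cv=0.0, replicate_cv=0.0)


@pytest.fixture(scope="session")
def prepost_records():
    """The standard PRE/POST design: triplicate samples x 10 cycles/class."""
    return simulate_dataset(
        [("W390", "PRE", 3, 10), ("W390", "POST", 3, 10)], seed=42
    )


@pytest.fixture(scope="session")
def prepost_features(prepost_records):
    from doughnose.features import featurize_dataset

    return featurize_dataset(prepost_records)


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)
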
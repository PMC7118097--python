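import numpy as np
import pytest

from wristnms.musculoskeletal import default_wrist_model
from wristnms.synthetic_data import CorruptionSpec, DatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def model():
    return default_wrist_model()


@pytest.fixture(scope="session")
def small_config():
    """Reduced-size dataset config for fast integration tests."""
    return DatasetConfig(
        units_per_muscle=8,
        n_emg_channels=4,
        corruption=CorruptionSpec(0.05, 0.1, 0.2),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, seed=42)


@pytest.fixture(scope="session")
def clean_dataset():
    """Uncorrupted, EMG-free dataset for spike/assignment tests."""
    cfg = DatasetConfig(
        units_per_muscle=10,
        corruption=CorruptionSpec(0.0, 0.0, 0.0),
        include_emg=False,
    )
    return generate_dataset(cfg, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
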
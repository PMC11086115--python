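import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fatigue_table():
    """Small synthetic fatigue cohort as a windowed feature table.

    6 subjects x (3 N + 3 Y) segments of 110 s (50 s after trimming),
    30 s windows stepped by 5 s -> 180 rows x 25 features + metadata.
    """
    from fatigueforest.config import DEFAULT_CONFIG
    from fatigueforest.fusion import dataset_feature_table
    from fatigueforest.simulate import SimulationSpec, generate_dataset

    cfg = DEFAULT_CONFIG.with_(step=5.0)
    spec = SimulationSpec(n_subjects=6, segments_per_state=(3, 3),
                          duration=110.0, seed=20240901)
    segments, _ = generate_dataset(spec, config=cfg)
    return dataset_feature_table(segments, config=cfg)


@pytest.fixture(scope="session")
def fatigue_Xy(fatigue_table):
    from fatigueforest.features import FEATURE_NAMES

    X = fatigue_table[list(FEATURE_NAMES)].to_numpy()
    y = fatigue_table["label"].to_numpy()
    return X, y
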
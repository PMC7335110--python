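import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from shuttlecsd.features import build_feature_table
from shuttlecsd.signal import default_layer_map
from shuttlecsd.synthetic import CohortConfig, iter_cohort_trials


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def layer_map32():
    return default_layer_map(32)


@pytest.fixture(scope="session")
def probe_cohort_cfg():
    """Small discrimination-phase cohort at reduced sampling rate.

    Kept cheap (3 subjects x 40 trials, 500 Hz) so qualitative generator
    properties can be checked in seconds.
    """
    return CohortConfig(
        n_subjects=3, sessions_per_phase=1, trials_per_session=40,
        fs_hz=500.0, phases=("discrimination",), seed=7,
    )


@pytest.fixture(scope="session")
def probe_features(probe_cohort_cfg):
    cfg = probe_cohort_cfg
    features, rejections = build_feature_table(
        iter_cohort_trials(cfg), cfg.layer_map()
    )
    return features, rejections
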
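import numpy as np
import pytest

from eegfusion.preprocess import PreprocessConfig
from eegfusion.synthetic_data import CohortSpec, default_class_specs, generate_cohort
from eegfusion.training_eval import build_cpd_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects per class, 60 s at 200 Hz, strongly separated spectra."""
    spec = CohortSpec(n_subjects_per_class=2, duration_s=60.0, fs=200.0, seed=7)
    return generate_cohort(spec, default_class_specs(1.0))


@pytest.fixture(scope="session")
def fast_pre_cfg():
    """Non-overlapping STFT frames: 3 frames per 3-s piece, 60 CPD columns."""
    return PreprocessConfig(overlap=0.0)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, fast_pre_cfg):
    return build_cpd_dataset(small_cohort, fast_pre_cfg)
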
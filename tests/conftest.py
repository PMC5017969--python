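import numpy as np
import pytest

from semgvowel.preprocessing import preprocess
from semgvowel.signal_io import Trial
from semgvowel.synthetic import (
    GeneratorConfig,
    generate_dataset,
    generate_trial,
    make_class_specs,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gen_config():
    return GeneratorConfig(n_subjects=1, trials_per_class=1, seed=7)


@pytest.fixture
def class_specs(gen_config):
    return make_class_specs(gen_config.n_classes, gen_config.seed)


@pytest.fixture
def clean_trial(class_specs, gen_config):
    rng = np.random.default_rng(99)
    return generate_trial(class_specs[2], gen_config, rng)


@pytest.fixture
def preprocessed_trial(clean_trial):
    return preprocess(clean_trial)


@pytest.fixture
def noise_trial(rng):
    return Trial(rng.standard_normal(1000), fs=1000.0, class_id=1,
                 subject_id="S01")


@pytest.fixture(scope="session")
def small_dataset():
    """1 subject x 11 classes x 3 trials: enough for io/selection tests."""
    cfg = GeneratorConfig(n_subjects=1, trials_per_class=3, seed=7)
    trials, meta = generate_dataset(cfg)
    return cfg, trials, meta
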
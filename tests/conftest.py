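import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

from pathshap import features, synthetic


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 train + 1 test subjects, 6 events/category, short scan: fast."""
    truth = synthetic.GroundTruth.default()
    return synthetic.gen_cohort(
        truth=truth, n_train=2, n_test=1, seed=11,
        n_per_category=6, n_volumes=100,
    )


@pytest.fixture(scope="session")
def tiny_instances(tiny_cohort):
    inst = features.build_instances(tiny_cohort)
    train_df, test_df = features.split_instances(inst)
    return features.standardize(train_df, test_df)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
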
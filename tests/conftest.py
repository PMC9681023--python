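import numpy as np
import pytest

import primflow as pf
from primflow import seq2seq_model as s2s


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A tiny synthetic dataset shared by fast tests (3 subjects)."""
    cfg = pf.SyntheticConfig(
        seed=42,
        n_subjects=4,
        trials_per_subject=2,
        trial_duration_s=8.0,
        split=(2, 1, 1),
    )
    return pf.generate_dataset(cfg)


@pytest.fixture()
def one_trial(small_dataset):
    return small_dataset.trials[0]


@pytest.fixture(scope="session")
def tiny_model_config():
    """A model geometry small enough for sub-second forward/backward."""
    return s2s.ModelConfig(
        hidden=8,
        embed_dim=8,
        window_s=1.0,
        core_s=0.6,
        train_slide_s=0.2,
        test_slide_s=0.6,
        max_epochs=2,
        batch_size=4,
        seed=7,
    )
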
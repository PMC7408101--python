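import numpy as np
import pytest

from plscv import SimConfig, encode_labels, generate, split


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw at the study's default conditions (2000 x 360, rank 2)."""
    return generate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def cal_split(default_dataset):
    """(X_cal, labels_cal, X_test, labels_test) at the default stride."""
    return split(default_dataset)


@pytest.fixture(scope="session")
def cal_xy(cal_split):
    """(X_cal, y_cal, labels_cal) with the dummy-coded response."""
    X_cal, labels_cal, _, _ = cal_split
    y, _ = encode_labels(labels_cal)
    return X_cal, y, labels_cal
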
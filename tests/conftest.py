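import numpy as np
import pytest

from sigunet import SyntheticSpec, encode_records, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """40 labelled synthetic records (16 SP / 12 TM / 12 other), fixed seed."""
    return generate_dataset(SyntheticSpec(n_sp=16, n_tm=12, n_other=12, seed=123))


@pytest.fixture(scope="session")
def small_samples(small_dataset):
    return encode_records(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_probs(rng, n_rows=96):
    """Random row-normalised (n_rows, 3) probability matrix."""
    p = rng.random((n_rows, 3)) + 1e-9
    return p / p.sum(axis=1, keepdims=True)
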
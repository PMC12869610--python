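import warnings

import numpy as np
import pytest

from cogmix import mixture as mx
from cogmix import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    return sd.default_generator_config()


@pytest.fixture(scope="session")
def true_model(default_config):
    return default_config.true_model()


@pytest.fixture(scope="session")
def small_dataset(default_config):
    """A modest default-condition draw shared across tests."""
    return sd.generate(default_config, N=400, seed=11)


@pytest.fixture(scope="session")
def small_data(small_dataset):
    return mx.records_to_arrays(small_dataset.records)


@pytest.fixture(scope="session")
def recovery_fit(default_config):
    """Full-tolerance fit at the parameter-recovery study size (N=3000,
    seed 1), shared between the round-trip and recovery tests."""
    ds = sd.generate(default_config, N=3000, seed=1)
    data = mx.records_to_arrays(ds.records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fr = mx.fit_em(data, seed=1)
    return ds, fr


@pytest.fixture(scope="session")
def fitted_small(small_data):
    """One semi-supervised fit on the shared dataset (looser tolerance so
    the session-wide fixture stays cheap)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return mx.fit_em(small_data, seed=11, tol=1e-6, max_iter=300)
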
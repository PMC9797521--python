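"""Shared fixtures: one solved synthetic bundle reused across test modules."""
import numpy as np
import pytest

from hipload.dynamics import params_from_anatomy
from hipload.synthetic import ToyConfig, generate_static_trial, generate_trial, toy_anatomy


@pytest.fixture(scope="session")
def toy_config():
    return ToyConfig(n_segments=5, include_cylinder=True, duration_s=0.3,
                     rate=50.0, seed=1)


@pytest.fixture(scope="session")
def toy(toy_config):
    return toy_anatomy(toy_config)


@pytest.fixture(scope="session")
def toy_bundle(toy, toy_config):
    """(marker trial, grf, ground truth) with oracle-solved ground truth."""
    return generate_trial(toy, toy_config)


@pytest.fixture(scope="session")
def toy_static(toy, toy_config):
    return generate_static_trial(toy, toy_config)


@pytest.fixture(scope="session")
def toy_params(toy):
    return params_from_anatomy(toy)
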
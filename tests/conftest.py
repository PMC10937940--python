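import numpy as np
import pytest

from neurogsp import (SyntheticSpec, default_basis, make_connectome,
                      make_signals)


@pytest.fixture(scope="session")
def small_spec():
    """A reduced synthetic study: 20 regions keeps eigen-solves instant."""
    return SyntheticSpec(n_regions=20, n_timepoints=128, seed=7)


@pytest.fixture(scope="session")
def small_graph(small_spec):
    return make_connectome(small_spec)


@pytest.fixture(scope="session")
def small_basis(small_spec):
    return default_basis(small_spec)


@pytest.fixture(scope="session")
def small_signal(small_basis, small_spec):
    ts, ratio = make_signals(small_basis, small_spec)
    return ts, ratio


@pytest.fixture(scope="session")
def study_spec():
    """Study-scale conditions: 55 regions."""
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def study_graph(study_spec):
    return make_connectome(study_spec)


@pytest.fixture(scope="session")
def study_basis(study_spec):
    return default_basis(study_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
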
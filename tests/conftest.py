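import numpy as np
import pytest

from lamella import synth


@pytest.fixture(scope="session")
def small_stack():
    """Default-condition stack, small lateral size for speed."""
    return synth.build_stack(synth.StackSpec(seed=7, lipids_per_leaflet=30))


@pytest.fixture(scope="session")
def default_stack():
    """Stack at the default study conditions (60 lipids/leaflet)."""
    return synth.build_stack(synth.StackSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
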
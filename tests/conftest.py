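import numpy as np
import pytest

from dosewarp.phantom import PhantomSpec, make_phantom, study_spec


@pytest.fixture(scope="session")
def default_pair():
    """One full-resolution phantom pair (96×96×48 @ 2 mm), fixed seed."""
    return make_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def study_pair():
    """One compact study-grid pair (64×64×32 @ 2.5 mm), fixed seed."""
    return make_phantom(study_spec(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
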
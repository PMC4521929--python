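import numpy as np
import pytest
from hypothesis import settings

from mobosim.geometry import (ShrinkingCircle, Dumbbell, DividingNucleus,
                              synthetic_division_frames)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def bench_circle():
    """The benchmark circle: radius 5 -> 3 over 5 s."""
    return ShrinkingCircle(r_s=5.0, r_e=3.0, t_e=5.0)


@pytest.fixture(scope="session")
def dumbbell_full():
    """Dumbbell with the published schedule (bridge grows after 200,000 s)."""
    return Dumbbell(R=3.0, d=0.5, L=0.01, T1=200000.0, T2=201000.0)


@pytest.fixture(scope="session")
def dumbbell_open():
    """Dumbbell already elongating from t=0; bridge length 10 at t=1000 s."""
    return Dumbbell(R=3.0, d=0.5, L=0.01, T1=0.0, T2=1000.0)


@pytest.fixture(scope="session")
def nucleus():
    return DividingNucleus(synthetic_division_frames())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
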
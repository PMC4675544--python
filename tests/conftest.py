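import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class ScriptedRNG:
    """Replays pre-recorded draws; used to feed identical randomness to the
    pure-python step functions and the compiled kernels."""

    def __init__(self, draws):
        self._draws = list(draws)

    def _pop(self):
        return np.asarray(self._draws.pop(0), dtype=float)

    def random(self, size=None):
        return self._pop()

    def uniform(self, low, high, size=None):
        return self._pop()

    def normal(self, loc, scale, size=None):
        return self._pop()


@pytest.fixture
def scripted_rng_cls():
    return ScriptedRNG
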
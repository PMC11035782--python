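import numpy as np
import pytest

import afwave


@pytest.fixture(scope="session")
def normal_trace():
    """A 10 s clean-ish normal-rhythm trace at 300 Hz."""
    return afwave.generate_ecg(afwave.normal_spec(duration_s=10.0, seed=7))


@pytest.fixture(scope="session")
def af_trace():
    """A 10 s AF trace at 300 Hz (irregular RR, no P, 7 Hz fibrillatory wave)."""
    return afwave.generate_ecg(afwave.af_spec(duration_s=10.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
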
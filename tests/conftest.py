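import numpy as np
import pytest

from thetagamma import AnalysisConfig, LfpTrace
from thetagamma.synth import GeneratorParams, generate_session


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture
def tone():
    """Factory for pure-tone traces: tone(freq, duration, fs, amp)."""

    def _make(freq, duration=10.0, fs=2000.0, amp=1.0, phase=0.0):
        t = np.arange(int(duration * fs)) / fs
        return LfpTrace(amp * np.cos(2 * np.pi * freq * t + phase), fs)

    return _make


@pytest.fixture(scope="session")
def small_session():
    """One modest synthetic session reused across read-only tests."""
    params = GeneratorParams(duration_s=120.0, fs=500.0, theta_occupancy=0.5,
                             modulation_depth=0.8, seed=1234)
    return generate_session(params)
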
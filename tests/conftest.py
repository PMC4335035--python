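import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tcrelay.traces import Trace

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def make_trace():
    """Factory for quick in-memory traces with sensible defaults."""

    def _make(samples, fs=100000.0, site="cortex", mode="TS",
              subject="s1", trial="t1", filtered=False):
        return Trace(subject_id=subject, trial_id=trial, site=site, mode=mode,
                     sampling_rate=fs, samples=np.asarray(samples, dtype=float),
                     filtered=filtered)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
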
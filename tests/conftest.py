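import numpy as np
import pytest

from ecgcycle import ecgsynth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_record():
    """One clean 8-lead record at a desk-friendly size (2500 samples)."""
    return ecgsynth.generate_clean(
        ecgsynth.RhythmSpec(heart_rate_bpm=72), duration_s=10.0, fs=250.0, seed=7
    )
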
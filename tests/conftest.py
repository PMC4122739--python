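import numpy as np
import pytest

from cohbias.spectral import TrialSegment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def white_noise_segments(n_trials, n_samples, rate, rng):
    return [
        TrialSegment(rng.standard_normal(n_samples), rate) for _ in range(n_trials)
    ]
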
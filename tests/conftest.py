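import numpy as np
import pytest

from eegemo import SynthSpec, decompose_bands, generate_recording, segment_windows, trim_lead
from eegemo.features import feature_tensor


TINY_SPEC = SynthSpec(
    n_subjects=2,
    n_trials_per_subject=4,
    n_channels=8,
    fs=128.0,
    duration=20.0,
    n_classes=2,
    n_latent_sources=4,
    effect_size=1.0,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_recording():
    """2 subjects x 4 trials x 8 channels x 20 s at 128 Hz."""
    return generate_recording(TINY_SPEC)


@pytest.fixture(scope="session")
def tiny_segments(tiny_recording):
    stack = decompose_bands(tiny_recording)
    return segment_windows(stack, 6.0, 3.0)


@pytest.fixture(scope="session")
def tiny_features(tiny_segments):
    return feature_tensor(tiny_segments, "pcc")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
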
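import numpy as np
import pytest

from hypoxeeg.preprocess import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_recording(
    data: np.ndarray, fs: float = 256.0, subject_id: str = "S01", condition: str = "sea"
) -> Recording:
    """Wrap a channels x samples array in a Recording with generic labels."""
    n_ch = data.shape[0]
    labels = [f"CH{i:02d}" for i in range(n_ch)]
    return Recording(
        data=data,
        fs=fs,
        channel_labels=labels,
        region_map={lab: "frontal" for lab in labels},
        subject_id=subject_id,
        condition=condition,
    )


@pytest.fixture
def sinusoid_recording():
    """One-channel 10 Hz unit-amplitude sinusoid, 60 s at 256 Hz."""
    fs = 256.0
    t = np.arange(int(60 * fs)) / fs
    return make_recording(np.sin(2 * np.pi * 10.0 * t)[None, :], fs=fs)
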
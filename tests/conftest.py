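import numpy as np
import pytest

from ieegflow.recording import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n_channels=4, fs=500.0, duration_s=64.0,
                   onset_s=None, n_soz=1, seed=0):
    """Random-noise recording helper with a valid SOZ annotation."""
    rng = np.random.default_rng(seed)
    n_samples = int(duration_s * fs)
    onset = int((onset_s if onset_s is not None else duration_s / 2) * fs)
    soz = np.zeros(n_channels, dtype=bool)
    soz[:n_soz] = True
    return Recording(
        data=rng.standard_normal((n_channels, n_samples)),
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(n_channels)],
        onset_sample=onset,
        soz_mask=soz,
        meta={"patient_id": "pt0", "seizure_id": "pt0_sz0"},
    )


@pytest.fixture
def noise_recording():
    return make_recording()
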
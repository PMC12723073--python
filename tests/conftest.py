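import numpy as np
import pytest

from tmsnet.recording import EpochedRecording


def make_recording(
    data: np.ndarray, fs_hz: float = 1000.0, t0_s: float = 0.0
) -> EpochedRecording:
    """Wrap a (channels, trials, samples) array with a uniform time axis
    starting at ``t0_s`` (which must place time 0 inside the epoch)."""
    data = np.asarray(data, dtype=float)
    n = data.shape[2]
    time_s = t0_s + np.arange(n) / fs_hz
    onset = int(round(-t0_s * fs_hz))
    return EpochedRecording(
        data=data,
        time_s=time_s,
        fs_hz=fs_hz,
        channel_labels=[f"CH{c:02d}" for c in range(data.shape[0])],
        onset_index=onset,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def volume_conduction_rec():
    from tmsnet.synthetic import volume_conduction_recording

    return volume_conduction_recording(seed=0)


@pytest.fixture(scope="session")
def vc_suite(volume_conduction_rec):
    """Both estimators on the volume-conduction scenario (prestimulus window,
    the longer one, for the largest COI-valid cell count)."""
    from tmsnet.connectivity import PRESTIMULUS, connectivity_suite

    return connectivity_suite(
        volume_conduction_rec,
        windows=(PRESTIMULUS,),
        estimators=("plv", "ciplv"),
    )
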
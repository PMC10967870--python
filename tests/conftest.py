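import numpy as np
import pytest

from eegstim.containers import Epoch, Recording
from eegstim.synthdata import DesignSpec

#: Paired 24-channel montage subset used where full-montage cost is not needed.
REDUCED_CHANNELS = (
    "Fz", "Cz", "Pz", "Oz",
    "FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1",
    "FC6", "FC4", "FC2", "C6", "C4", "C2", "CP6", "CP4", "CP2",
    "O1", "O2",
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_design():
    return DesignSpec(
        subjects_per_group=2,
        arms=("dominant",),
        muscle_unions=("ECU-ED",),
        schemes=("FVS-1", "NMES-2"),
        analyzed_channels=REDUCED_CHANNELS,
    )


def make_epoch(samples, rate=1000.0, labels=None, baseline=5.0, block=10.0,
               meta=None):
    """Build an Epoch on the standard [-baseline, block) axis."""
    samples = np.atleast_2d(np.asarray(samples, float))
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    n = samples.shape[1]
    time = (np.arange(n) - int(round(baseline * rate))) / rate
    return Epoch(samples=samples, time=time, rate=rate,
                 channel_labels=labels, meta=meta or {})


def make_recording(samples, rate=1000.0, labels=None, events=(), meta=None):
    samples = np.atleast_2d(np.asarray(samples, float))
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(samples.shape[0]))
    return Recording(samples=samples, rate=rate, channel_labels=labels,
                     events=list(events), meta=meta or {})
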
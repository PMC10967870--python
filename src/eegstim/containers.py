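"""Core in-memory containers: continuous recordings and 15-s analysis epochs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
    rate : float
        Sampling rate in Hz (1000 Hz in the emulated acquisition).
    channel_labels : tuple of str
        Ordered 10-10 names, unique.
    events : list of (int, str)
        (onset sample, scheme label) stimulation markers, strictly increasing.
    meta : dict
        Free-form provenance (subject, group, arm, union, scheme, ...).
    """

    samples: np.ndarray
    rate: float
    channel_labels: tuple
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel count mismatch between samples and labels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        onsets = [int(s) for s, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.samples.shape[1]):
            raise ValueError("event onset outside record")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def copy(self) -> "Recording":
        return replace(
            self,
            samples=self.samples.copy(),
            events=list(self.events),
            meta=dict(self.meta),
        )


@dataclass
class Epoch:
    """One stimulus-locked segment: 5-s baseline + 10-s stimulation block.

    ``time`` is in seconds relative to stimulation onset and spans [-5, 10)
    with half-open convention: baseline bins satisfy t < 0, block bins t >= 0
    (the onset sample belongs to the stimulation span).
    """

    samples: np.ndarray
    time: np.ndarray
    rate: float
    channel_labels: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.shape != (len(self.channel_labels), self.time.size):
            raise ValueError("epoch samples shape mismatch with labels/time")

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.time < 0.0

    @property
    def block_mask(self) -> np.ndarray:
        return self.time >= 0.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch") from None

    def copy(self) -> "Epoch":
        return replace(self, samples=self.samples.copy(), meta=dict(self.meta))
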
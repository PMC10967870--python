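"""Band-wise relative spectral power (RSP).

For each episode the RSP of a band is the difference between the band's
share of total 1–100 Hz power during the period of interest of the
stimulation block and the same share during the 5-s baseline:

    RSP_band = P_block(F1..F2)/P_block(1..100) - P_base(F1..F2)/P_base(1..100)

so every value lies in [-1, 1].  Bands follow the conventional table with a
deliberate 12–13 Hz gap between alpha and beta: theta [4, 8), alpha [8, 12),
beta [13, 30), gamma [30, 100) Hz.  The period of interest defaults to
0.30–0.75 s after onset, the window where P300 group differences concentrate.

PSD estimation: Hann-tapered periodogram zero-padded to a <=1 Hz grid for
short segments (< 4 s, e.g. the 0.45-s period of interest); Welch with 2-s
Hann segments and 50% overlap for longer ones (the 5-s baseline).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import Epoch
from .montage import sensorimotor_set

#: Frequency bands [F1, F2) in Hz.
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 100.0),
}

#: Total analysis range for the normalizing integral.
TOTAL_RANGE = (1.0, 100.0)

#: Default period of interest (s after stimulation onset).
PERIOD_OF_INTEREST = (0.30, 0.75)


def compute_psd(segment: np.ndarray, rate: float, method: str = "auto"):
    """Power spectral density per channel on a uniform grid (<= 1 Hz steps).

    Returns ``(freqs, psd)`` with ``psd`` in µV²/Hz, non-negative, and
    Parseval-consistent (grid integral ~ signal variance).
    """
    x = np.atleast_2d(np.asarray(segment, float))
    n = x.shape[-1]
    if n < 0.25 * rate:
        raise ValueError("segment shorter than 0.25 s")
    if method == "auto":
        method = "welch" if n >= 4 * rate else "periodogram"
    if method == "periodogram":
        nfft = max(n, int(round(rate)))  # zero-pad to a <= 1 Hz grid
        freqs, psd = signal.periodogram(x, fs=rate, window="hann", nfft=nfft,
                                        detrend=False, axis=-1)
    elif method == "welch":
        nper = min(n, int(round(2 * rate)))
        freqs, psd = signal.welch(x, fs=rate, window="hann", nperseg=nper,
                                  noverlap=nper // 2, detrend=False, axis=-1)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return freqs, psd


def band_fraction(freqs: np.ndarray, psd: np.ndarray, band: tuple,
                  total: tuple = TOTAL_RANGE) -> np.ndarray:
    """Fraction of total-range power inside ``[F1, F2)``, per channel."""
    psd = np.atleast_2d(psd)
    bmask = (freqs >= band[0]) & (freqs < band[1])
    tmask = (freqs >= total[0]) & (freqs <= total[1])
    denom = psd[:, tmask].sum(axis=-1)
    if np.any(denom <= 0):
        raise ValueError("zero total power in the 1-100 Hz range")
    return psd[:, bmask].sum(axis=-1) / denom


def compute_rsp(epoch: Epoch, band: str | tuple,
                period_of_interest: tuple = PERIOD_OF_INTEREST,
                baseline_mode: str = "full") -> np.ndarray:
    """Per-channel RSP of one epoch for one band.

    ``baseline_mode='full'`` uses the whole 5-s baseline for the reference
    spectrum; ``'matched'`` uses a duration-matched slice ending at onset.
    """
    if isinstance(band, str):
        band = BANDS[band]
    t = epoch.time
    p0, p1 = period_of_interest
    if p0 < 0 or p1 > t.max() + 1.0 / epoch.rate:
        raise ValueError("period of interest outside the stimulation span")
    block = epoch.samples[:, (t >= p0) & (t < p1)]
    if baseline_mode == "full":
        base = epoch.samples[:, epoch.baseline_mask]
    elif baseline_mode == "matched":
        base = epoch.samples[:, (t >= -(p1 - p0)) & (t < 0)]
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    fb, pb = compute_psd(block, epoch.rate)
    fs_, ps = compute_psd(base, epoch.rate)
    return band_fraction(fb, pb, band) - band_fraction(fs_, ps, band)


def region_channels(region: str, labels, stimulated_side: str | None = None):
    """Resolve a region name to a channel tuple (post-flip frame).

    ``'whole-brain'`` is every analyzed channel; ``'contralateral-
    sensorimotor'`` is the sensorimotor set on the hemisphere opposite the
    stimulated arm.
    """
    labels = tuple(labels)
    if region == "whole-brain":
        return labels
    if region == "contralateral-sensorimotor":
        if stimulated_side not in ("left", "right"):
            raise ValueError("stimulated side required for the contralateral region")
        contra = "left" if stimulated_side == "right" else "right"
        chans = tuple(c for c in sensorimotor_set(contra) if c in labels)
        if not chans:
            raise ValueError("contralateral sensorimotor set is empty in this montage")
        return chans
    raise ValueError(f"unknown region {region!r}")


def aggregate_rsp(values: np.ndarray, labels, region: str,
                  stimulated_side: str | None = None) -> float:
    """Unweighted mean of per-channel RSP over a region, then over blocks.

    ``values`` is (n_channels,) for one epoch or (n_blocks, n_channels).
    """
    labels = tuple(labels)
    values = np.atleast_2d(np.asarray(values, float))
    chans = region_channels(region, labels, stimulated_side)
    idx = [labels.index(c) for c in chans]
    return float(values[:, idx].mean())
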
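"""Time–frequency analysis: ERSP with a baseline-permutation mask, ERD/ERS.

Power is decomposed with Morlet wavelets (1-Hz grid, ``n_cycles =
max(3, f/2)``).  The ERSP z-normalizes block power by the per-frequency mean
and SD of the same epoch's baseline bins:

    ERSP(f, t) = (S(f, t) - mu_base(f)) / sd_base(f)

Bins whose wavelet support crosses the epoch edge are flagged invalid and
excluded from the baseline statistics.  Significance of the across-blocks
mean ERSP is assessed by resampling surrogate block-mean values from the
pooled baseline bins of each frequency (default 2000 draws), two-sided
empirical p values, and Benjamini–Hochberg FDR at 0.05 across all bins.

The ERD/ERS summary of a channel is the mean ERSP over a band-by-latency
window (K time–frequency bins), negative for desynchronization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import BANDS

#: Default wavelet frequency grid (Hz).
DEFAULT_FREQS = np.arange(2.0, 101.0, 1.0)


def n_cycles_rule(freqs: np.ndarray) -> np.ndarray:
    return np.maximum(3.0, np.asarray(freqs, float) / 2.0)


@dataclass
class TFR:
    """Single-channel wavelet power: frequency x time, µV²."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray       # bool, False where edge-contaminated
    channel: str = ""


@dataclass
class ERSPMap:
    """Baseline-z-normalized time–frequency map with significance mask."""

    values: np.ndarray      # frequency x time, z units
    freqs: np.ndarray
    times: np.ndarray
    valid: np.ndarray
    mask: np.ndarray | None = None   # True where corrected p <= alpha
    channel: str = ""
    meta: dict = field(default_factory=dict)


def compute_tfr(series: np.ndarray, rate: float, times: np.ndarray,
                freqs: np.ndarray = DEFAULT_FREQS, decim: int = 10,
                channel: str = "") -> TFR:
    """Morlet-wavelet power of one epoch channel.

    ``decim`` downsamples the time axis of the output (power varies slowly
    relative to the 1000-Hz raw grid).  Edge-contaminated bins — those whose
    wavelet half-support extends beyond the epoch — are flagged invalid.
    """
    arr = np.asarray(series, float)
    out = compute_tfr_multi(arr[None, None, :], rate, times, freqs=freqs,
                            decim=decim)
    power, t_dec, valid = out
    return TFR(power=power[0, 0], freqs=np.asarray(freqs, float),
               times=t_dec, valid=valid, channel=channel)


def compute_tfr_multi(data: np.ndarray, rate: float, times: np.ndarray,
                      freqs: np.ndarray = DEFAULT_FREQS, decim: int = 10):
    """Vectorized Morlet power for (n_epochs, n_channels, n_times) data.

    Returns ``(power, decimated_times, valid_mask)`` with power in µV².
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.asarray(freqs, float)
    if rate <= 2 * freqs.max():
        raise ValueError(f"rate {rate} Hz too low for a {freqs.max()} Hz wavelet")
    cycles = n_cycles_rule(freqs)
    power = tfr_array_morlet(np.asarray(data, float), sfreq=rate, freqs=freqs,
                             n_cycles=cycles, output="power", decim=decim,
                             verbose="error")
    t_dec = np.asarray(times, float)[::decim]
    half_support = cycles / (2.0 * freqs)       # seconds
    t0, t1 = times[0], times[-1]
    valid = ((t_dec[None, :] >= t0 + half_support[:, None])
             & (t_dec[None, :] <= t1 - half_support[:, None]))
    return power, t_dec, valid


def compute_ersp(tfr: TFR, baseline_span: tuple = (-5.0, 0.0),
                 min_baseline_bins: int = 10) -> ERSPMap:
    """Z-normalize block power by the epoch's own baseline statistics."""
    base = (tfr.times >= baseline_span[0]) & (tfr.times < baseline_span[1])
    usable = base[None, :] & tfr.valid
    n_base = usable.sum(axis=1)
    if np.any(n_base < min_baseline_bins):
        bad = tfr.freqs[n_base < min_baseline_bins]
        raise ValueError(f"fewer than {min_baseline_bins} uncontaminated "
                         f"baseline bins at {bad[0]:g} Hz")
    mu = np.array([tfr.power[i, usable[i]].mean() for i in range(len(tfr.freqs))])
    sd = np.array([tfr.power[i, usable[i]].std(ddof=1) for i in range(len(tfr.freqs))])
    zero = sd <= 0
    if np.any(zero):
        raise ValueError(f"zero baseline SD at {tfr.freqs[zero][0]:g} Hz")
    values = (tfr.power - mu[:, None]) / sd[:, None]
    return ERSPMap(values=values, freqs=tfr.freqs.copy(), times=tfr.times.copy(),
                   valid=tfr.valid.copy(), channel=tfr.channel)


def baseline_permutation_mask(ersps: list[ERSPMap], n_perm: int = 2000,
                              alpha: float = 0.05, seed=None) -> np.ndarray:
    """FDR-corrected significance mask for the across-blocks mean ERSP.

    The null for each frequency is built by drawing, ``n_perm`` times, one
    surrogate value per block from that block's pooled baseline bins and
    averaging them — i.e. surrogate "block means" under the hypothesis that
    block bins behave like baseline bins.  Two-sided empirical p values use
    the (b+1)/(n_perm+1) convention; Benjamini–Hochberg FDR is applied
    across all valid time–frequency bins.
    """
    import warnings

    from statsmodels.stats.multitest import multipletests

    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse null distribution")
    if len(ersps) < 2:
        raise ValueError("at least two blocks are required")
    rng = np.random.default_rng(seed)
    ref = ersps[0]
    n_blocks = len(ersps)
    stack = np.stack([e.values for e in ersps])          # blocks x f x t
    valid = np.logical_and.reduce([e.valid for e in ersps])
    obs = stack.mean(axis=0)                             # f x t

    n_f, n_t = obs.shape
    pvals = np.ones((n_f, n_t))
    base_mask = ref.times < 0
    for i in range(n_f):
        pools = [e.values[i, base_mask & e.valid[i]] for e in ersps]
        if any(p.size == 0 for p in pools):
            continue
        draws = np.empty((n_perm, n_blocks))
        for b, pool in enumerate(pools):
            draws[:, b] = pool[rng.integers(0, pool.size, size=n_perm)]
        null = np.abs(draws.mean(axis=1))
        null.sort()
        cols = np.flatnonzero(valid[i])
        b_ge = null.size - np.searchsorted(null, np.abs(obs[i, cols]), side="left")
        pvals[i, cols] = (b_ge + 1) / (n_perm + 1)

    flat = pvals[valid]
    rej = np.zeros_like(pvals, dtype=bool)
    if flat.size:
        rej_flat = multipletests(flat, alpha=alpha, method="fdr_bh")[0]
        rej[valid] = rej_flat
    return rej


def compute_erd_ers(ersp: ERSPMap, band: str | tuple, window: tuple,
                    stat: str = "mean") -> tuple[float, int]:
    """ERD/ERS summary of one channel: mean (or peak) ERSP over band x window.

    Returns ``(value, K)`` with K the number of time–frequency bins in the
    window.  ``stat='peak'`` returns the bin with the largest magnitude,
    keeping its sign.
    """
    if isinstance(band, str):
        band = BANDS[band]
    fmask = (ersp.freqs >= band[0]) & (ersp.freqs < band[1])
    tmask = (ersp.times >= window[0]) & (ersp.times < window[1])
    if not fmask.any() or not tmask.any():
        raise ValueError("empty band x latency window")
    vals = ersp.values[np.ix_(fmask, tmask)]
    k = vals.size
    if stat == "mean":
        return float(vals.mean()), k
    if stat == "peak":
        flat = vals.ravel()
        return float(flat[np.argmax(np.abs(flat))]), k
    raise ValueError(f"unknown stat {stat!r}")


def erd_ers_topography(epoch_tfrs: dict, band: str | tuple, window: tuple,
                       stat: str = "mean") -> dict:
    """Per-channel ERD/ERS map from {channel: ERSPMap}."""
    return {ch: compute_erd_ers(e, band, window, stat=stat)[0]
            for ch, e in epoch_tfrs.items()}
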
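"""Event-related potentials and P300 peak features.

The ERP of an episode is the stimulation-block waveform minus the scalar
mean of the baseline span, per channel.  The P300 waveform is the unweighted
average of the Fz, Cz and Pz ERPs; its peak amplitude (µV relative to
baseline) and latency (s after stimulation onset) are taken as the maximum
within a configurable search window, 250–800 ms by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Epoch
from .montage import MIDLINE_P300

#: Default P300 search window (s after onset).
P300_WINDOW = (0.25, 0.80)


@dataclass
class ERPWaveform:
    values: np.ndarray          # channels x time, µV
    time: np.ndarray            # s, stimulation span [0, 10)
    channel_labels: tuple
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class P300Feature:
    peak_amplitude: float       # µV relative to baseline
    peak_latency: float         # s after stimulation onset


def compute_erp(epoch: Epoch) -> ERPWaveform:
    """Baseline-correct one epoch: block waveform minus baseline mean."""
    base = epoch.baseline_mask
    if not base.any():
        raise ValueError("epoch has a zero-length baseline span")
    block = epoch.block_mask
    baseline_mean = epoch.samples[:, base].mean(axis=-1, keepdims=True)
    return ERPWaveform(values=epoch.samples[:, block] - baseline_mean,
                       time=epoch.time[block].copy(),
                       channel_labels=epoch.channel_labels,
                       meta=dict(epoch.meta))


def midline_p300(erp: ERPWaveform, channels=MIDLINE_P300) -> ERPWaveform:
    """Unweighted mean of the Fz/Cz/Pz ERPs -> 1 x time P300 waveform."""
    rows = []
    for lab in channels:
        if lab not in erp.channel_labels:
            raise ValueError(f"midline channel {lab!r} missing from ERP")
        rows.append(erp.values[erp.channel_labels.index(lab)])
    mean = np.mean(rows, axis=0)
    return ERPWaveform(values=mean[None, :], time=erp.time.copy(),
                       channel_labels=("P300",), meta=dict(erp.meta))


def extract_p300(p300: ERPWaveform | np.ndarray, time: np.ndarray | None = None,
                 window: tuple = P300_WINDOW, smooth_s: float = 0.0) -> P300Feature:
    """Peak amplitude and latency of the P300 waveform within ``window``.

    The peak is the maximum sample; ties resolve to the earliest time.
    ``smooth_s`` > 0 applies a centred moving average of that duration
    before peak picking (off by default: peak means peak).
    """
    if isinstance(p300, ERPWaveform):
        values = p300.values[0] if p300.values.ndim == 2 else p300.values
        time = p300.time
    else:
        values = np.asarray(p300, float).ravel()
        if time is None:
            raise ValueError("time axis required for array input")
    if smooth_s > 0:
        dt = float(np.median(np.diff(time)))
        k = max(1, int(round(smooth_s / dt)))
        kernel = np.ones(k) / k
        values = np.convolve(values, kernel, mode="same")
    mask = (time >= window[0]) & (time <= window[1])
    if not mask.any():
        raise ValueError(f"P300 window {window} is empty after clipping")
    vals = values[mask]
    twin = time[mask]
    k = int(np.argmax(vals))  # argmax returns the first (earliest) maximum
    return P300Feature(peak_amplitude=float(vals[k]), peak_latency=float(twin[k]))


def average_waveforms(waves: list[ERPWaveform]) -> ERPWaveform:
    """Average ERPs across repeated blocks (the per-participant reading unit)."""
    if not waves:
        raise ValueError("no waveforms to average")
    t0 = waves[0].time
    for w in waves[1:]:
        if w.time.shape != t0.shape or not np.allclose(w.time, t0):
            raise ValueError("waveforms have mismatched time axes")
    values = np.mean([w.values for w in waves], axis=0)
    return ERPWaveform(values=values, time=t0.copy(),
                       channel_labels=waves[0].channel_labels,
                       meta={**waves[0].meta, "n_averaged": len(waves)})


def erp_cluster_compare(erps_a: list, erps_b: list, paired: bool = False,
                        n_perm: int = 2000, cluster_alpha: float = 0.05,
                        alpha: float = 0.05, seed=None):
    """Cluster-based permutation comparison of two ERP conditions over time.

    Each argument is a list of 1-D waveforms (or 1-channel ERPWaveforms) on a
    common time axis.  Returns a list of significant spans
    ``(start_s, end_s, p)`` plus the full ClusterTestResult.
    """
    from . import stats as _stats

    def _stack(erps):
        rows, times = [], []
        for w in erps:
            if isinstance(w, ERPWaveform):
                rows.append(w.values[0] if w.values.ndim == 2 else w.values)
                times.append(w.time)
            else:
                rows.append(np.asarray(w, float))
                times.append(None)
        return np.array(rows), times

    a, ta = _stack(erps_a)
    b, tb = _stack(erps_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions have mismatched time axes")
    time = next((t for t in ta + tb if t is not None), None)
    for t in ta + tb:
        if t is not None and not np.allclose(t, time):
            raise ValueError("conditions have mismatched time axes")
    res = _stats.cluster_permutation(a, b, dimension="time", paired=paired,
                                     n_perm=n_perm, cluster_alpha=cluster_alpha,
                                     alpha=alpha, seed=seed)
    spans = []
    for cl in res.clusters:
        if cl.p <= alpha:
            idx = np.asarray(cl.members)
            if time is not None:
                spans.append((float(time[idx.min()]), float(time[idx.max()]), cl.p))
            else:
                spans.append((int(idx.min()), int(idx.max()), cl.p))
    return spans, res
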
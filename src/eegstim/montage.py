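"""62-channel 10-10 montage: labels, mirror pairs, 2-D positions, spatial adjacency.

The analyzed montage is a standard 64-electrode cap with the reference (FCz)
and ground (AFz) excluded, leaving 62 recorded channels.  Left-hemisphere
labels carry odd digits, right-hemisphere labels even digits, and midline
labels end in "z"; mirror partners differ only in the digit (1<->2, 3<->4,
5<->6, 7<->8, 9<->10).
"""

from __future__ import annotations

import re
from functools import lru_cache

import numpy as np

#: Default 62 analyzed channels (10-10 names, cap order).
CHANNELS_62: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)

#: Sensorimotor region of interest, left hemisphere; mirror gives the right.
SENSORIMOTOR_LEFT: tuple[str, ...] = (
    "FC5", "FC3", "FC1", "C5", "C3", "C1", "CP5", "CP3", "CP1",
)

#: Midline channels averaged for the P300 waveform.
MIDLINE_P300: tuple[str, ...] = ("Fz", "Cz", "Pz")

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def is_midline(label: str) -> bool:
    m = _LABEL_RE.match(label)
    return bool(m) and m.group(2) == "z"


def mirror_label(label: str) -> str:
    """Mirror a 10-10 label across the mid-sagittal plane (C3 -> C4).

    Midline labels map to themselves.  Raises ``ValueError`` for labels that
    do not follow the prefix+digit convention.
    """
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse 10-10 label: {label!r}")
    prefix, suffix = m.groups()
    if suffix == "z":
        return label
    n = int(suffix)
    partner = n - 1 if n % 2 == 0 else n + 1
    return f"{prefix}{partner}"


def mirror_pairs(labels=CHANNELS_62) -> list[tuple[str, str]]:
    """All (left, right) mirror pairs present in ``labels``.

    Raises ``ValueError`` listing any lateral label whose partner is absent.
    """
    labelset = set(labels)
    missing = []
    pairs = []
    for lab in labels:
        if is_midline(lab):
            continue
        partner = mirror_label(lab)
        if partner not in labelset:
            missing.append(lab)
        elif int(_LABEL_RE.match(lab).group(2)) % 2 == 1:  # left member once
            pairs.append((lab, partner))
    if missing:
        raise ValueError(f"unpaired lateral labels: {missing}")
    return pairs


def sensorimotor_set(side: str) -> tuple[str, ...]:
    """Sensorimotor channel set on the given hemisphere ('left' | 'right')."""
    if side == "left":
        return SENSORIMOTOR_LEFT
    if side == "right":
        return tuple(mirror_label(c) for c in SENSORIMOTOR_LEFT)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@lru_cache(maxsize=4)
def positions_2d(labels: tuple[str, ...] = CHANNELS_62) -> np.ndarray:
    """2-D projected electrode coordinates, one row per label.

    Uses the standard 10-05 template positions (via MNE) and projects to the
    x-y plane, which is adequate for neighbourhood construction and simple
    topographic scatter plots.
    """
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in pos]
    if missing:
        raise ValueError(f"labels not in 10-05 template: {missing}")
    xyz = np.array([pos[lab] for lab in labels])
    # azimuthal-style flattening: keep x, y, stretch outer rings by z deficit
    xy = xyz[:, :2].copy()
    return xy


def neighbor_graph(labels=CHANNELS_62, prune_quantile: float = 0.90) -> dict[str, set[str]]:
    """Channel adjacency from Delaunay triangulation of the 2-D positions.

    Edges longer than the ``prune_quantile`` of edge lengths are removed so
    the hull does not link distant temporal/occipital sites.  The result is
    symmetric, has no self-loops, and is verified to be connected.
    """
    from scipy.spatial import Delaunay

    labels = tuple(labels)
    xy = positions_2d(labels)
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = simplex[i], simplex[(i + 1) % 3]
            edges.add((min(a, b), max(a, b)))
    lengths = {e: np.linalg.norm(xy[e[0]] - xy[e[1]]) for e in edges}
    cutoff = np.quantile(list(lengths.values()), prune_quantile)
    graph: dict[str, set[str]] = {lab: set() for lab in labels}
    for (a, b), ln in lengths.items():
        if ln <= cutoff:
            graph[labels[a]].add(labels[b])
            graph[labels[b]].add(labels[a])
    _assert_graph_ok(graph)
    return graph


def plot_topomap(values: dict[str, float], ax=None, cmap: str = "RdBu_r",
                 annotate: bool = True):
    """Simple scatter-on-layout topographic plot of per-channel values.

    Requires matplotlib (the ``plot`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    labels = tuple(values)
    xy = positions_2d(labels)
    vals = np.array([values[lab] for lab in labels])
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    lim = np.abs(vals).max() or 1.0
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, s=180, cmap=cmap,
                    vmin=-lim, vmax=lim, edgecolors="k", linewidths=0.5)
    if annotate:
        for (x, y), lab in zip(xy, labels):
            ax.annotate(lab, (x, y), ha="center", va="center", fontsize=5)
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax


def _assert_graph_ok(graph: dict[str, set[str]]) -> None:
    for lab, nbrs in graph.items():
        if lab in nbrs:
            raise AssertionError(f"self-neighbor at {lab}")
        for n in nbrs:
            if lab not in graph[n]:
                raise AssertionError(f"asymmetric edge {lab}-{n}")
    # connectivity
    labels = list(graph)
    seen = {labels[0]}
    stack = [labels[0]]
    while stack:
        for n in graph[stack.pop()]:
            if n not in seen:
                seen.add(n)
                stack.append(n)
    if len(seen) != len(labels):
        raise AssertionError("neighbor graph is not connected")
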
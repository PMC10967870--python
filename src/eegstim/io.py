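"""Reading and writing continuous recordings and epoch stores.

Readers go through MNE (BrainVision ``.vhdr`` triplets and EDF/EDF+).
Writers are implemented here: a BrainVision writer emitting IEEE float-32
multiplexed binary with a marker file, and an EDF+ writer with 16-bit
physical scaling and an annotation channel carrying the stimulation markers.
Both produce files MNE can read back, which the tests use as an independent
round-trip check.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .containers import Epoch, Recording

_BV_HEADER = """Brain Vision Data Exchange Header File Version 1.0
; Written by eegstim

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_ch}
SamplingInterval={interval:g}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
"""

_BV_MARKER_HEADER = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,00000000000000000000
"""


def write_brainvision(rec: Recording, path) -> Path:
    """Write ``<path>.vhdr/.vmrk/.eeg``; returns the ``.vhdr`` path."""
    path = Path(path)
    if path.suffix == ".vhdr":
        path = path.with_suffix("")
    stem = path.name
    path.parent.mkdir(parents=True, exist_ok=True)

    header = _BV_HEADER.format(stem=stem, n_ch=rec.n_channels,
                               interval=1e6 / rec.rate)
    lines = [header]
    for i, lab in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={lab},,1,µV\n")
    (path.parent / f"{stem}.vhdr").write_text("".join(lines), encoding="utf-8")

    mlines = [_BV_MARKER_HEADER.format(stem=stem)]
    for k, (onset, label) in enumerate(rec.events, start=2):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{k}=Stimulus,{label},{int(onset) + 1},1,0\n")
    (path.parent / f"{stem}.vmrk").write_text("".join(mlines), encoding="utf-8")

    data = np.asarray(rec.samples, dtype="<f4").T  # multiplexed: time-major
    (path.parent / f"{stem}.eeg").write_bytes(data.tobytes())
    return path.parent / f"{stem}.vhdr"


def _edf_field(value, width) -> bytes:
    s = str(value)
    if len(s) > width:
        # compact float representation that still round-trips the header
        s = f"{float(value):.{max(1, width - 6)}g}"[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> Path:
    """Write an EDF+C file with an annotation channel for the markers.

    Samples are quantized to 16 bits over each channel's physical range;
    the quantization step is ``(pmax - pmin) / 65535``.  The recording
    duration must be an integral number of seconds (1-s data records).
    """
    path = Path(path).with_suffix(".edf")
    path.parent.mkdir(parents=True, exist_ok=True)
    n_records = rec.n_times / rec.rate
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError("EDF writer requires an integral number of seconds")
    n_records = int(round(n_records))
    spr = int(round(rec.rate))  # samples per 1-s record, per signal

    # annotation TALs: record 0 carries all events; others only timestamps
    tals = [b"+0\x14\x14\x00"]
    for onset, label in rec.events:
        t = onset / rec.rate
        tals.append(f"+{t:g}\x14{label}\x14\x00".encode("utf-8"))
    ann0 = b"".join(tals)
    ann_bytes = max(len(ann0) + 2, 24)
    ann_spr = (ann_bytes + 1) // 2  # 2 bytes per "sample"

    n_sig = rec.n_channels + 1
    pmins, pmaxs = [], []
    for c in range(rec.n_channels):
        lo, hi = float(rec.samples[c].min()), float(rec.samples[c].max())
        if hi - lo < 1e-6:
            lo, hi = lo - 1.0, hi + 1.0
        pmins.append(lo)
        pmaxs.append(hi)

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field("X X X X", 80)
    hdr += _edf_field("Startdate 01-JAN-2000 X eegstim X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (1 + n_sig), 8)
    hdr += _edf_field("EDF+C", 44)
    hdr += _edf_field(n_records, 8)
    hdr += _edf_field(1, 8)
    hdr += _edf_field(n_sig, 4)

    labels = [f"EEG {lab}" for lab in rec.channel_labels] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        ([""] * n_sig, 80),
        (["uV"] * rec.n_channels + [""], 8),
        ([f"{v:.7g}"[:8] for v in pmins] + ["-1"], 8),
        ([f"{v:.7g}"[:8] for v in pmaxs] + ["1"], 8),
        (["-32768"] * n_sig, 8),
        (["32767"] * n_sig, 8),
        ([""] * n_sig, 80),
        ([spr] * rec.n_channels + [ann_spr], 8),
        ([""] * n_sig, 32),
    ]
    for values, width in fields:
        for v in values:
            hdr += _edf_field(v, width)

    # re-read header-declared physical bounds so scaling matches exactly
    pmins = [float(f"{v:.7g}"[:8]) for v in pmins]
    pmaxs = [float(f"{v:.7g}"[:8]) for v in pmaxs]

    with open(path, "wb") as fh:
        fh.write(hdr)
        scale = [(pmaxs[c] - pmins[c]) / 65535.0 for c in range(rec.n_channels)]
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for c in range(rec.n_channels):
                dig = np.round((rec.samples[c, sl] - pmins[c]) / scale[c]) - 32768
                fh.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())
            tal = ann0 if r == 0 else f"+{r}\x14\x14\x00".encode("ascii")
            fh.write(tal.ljust(2 * ann_spr, b"\x00"))
    return path


def write_recording(rec: Recording, path, format: str = "brainvision") -> Path:
    if format == "brainvision":
        return write_brainvision(rec, path)
    if format in ("edf", "edf+"):
        return write_edf(rec, path)
    raise ValueError(f"unsupported format {format!r}")


def read_recording(path, format: str | None = None) -> Recording:
    """Read a BrainVision or EDF(+) recording into a :class:`Recording`.

    Samples are returned in µV; stimulation markers become ``events``
    (onset sample, scheme label), with BrainVision's ``Stimulus/`` and the
    EDF channel-name prefixes stripped.
    """
    import mne

    path = Path(path)
    fmt = format or {".vhdr": "brainvision", ".edf": "edf"}.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from {path.name!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif fmt in ("edf", "edf+"):
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported format {fmt!r}")
    data = raw.get_data() * 1e6  # V -> µV
    labels = tuple(lab.removeprefix("EEG ").strip() for lab in raw.ch_names)
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment") or desc.startswith("Edge"):
            continue
        label = desc.split("/", 1)[1] if desc.startswith("Stimulus/") else desc
        events.append((int(round(ann["onset"] * raw.info["sfreq"])), label))
    events.sort(key=lambda e: e[0])
    return Recording(samples=data, rate=float(raw.info["sfreq"]),
                     channel_labels=labels, events=events,
                     meta={"source": str(path)})


# ---------------------------------------------------------------------------
# epoch persistence (HDF5)
# ---------------------------------------------------------------------------

def save_epochs(epochs: list[Epoch], path) -> Path:
    """Persist epochs to HDF5: one group per epoch with metadata attributes."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        for i, ep in enumerate(epochs):
            g = fh.create_group(f"epoch_{i:05d}")
            g.create_dataset("samples", data=ep.samples, compression="gzip")
            g.create_dataset("time", data=ep.time)
            g.attrs["rate"] = ep.rate
            g.attrs["channel_labels"] = list(ep.channel_labels)
            for k, v in ep.meta.items():
                if v is not None:
                    g.attrs[f"meta_{k}"] = v
    return path


def load_epochs(path) -> list[Epoch]:
    import h5py

    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            g = fh[key]
            meta = {k.removeprefix("meta_"): (v.item() if hasattr(v, "item") else v)
                    for k, v in g.attrs.items() if k.startswith("meta_")}
            labels = tuple(lab.decode() if isinstance(lab, bytes) else str(lab)
                           for lab in g.attrs["channel_labels"])
            out.append(Epoch(samples=g["samples"][()], time=g["time"][()],
                             rate=float(g.attrs["rate"]),
                             channel_labels=labels, meta=meta))
    return out
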
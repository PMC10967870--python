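"""Synthetic factorial EEG study generator with known ground truth.

Emulates a two-group (stroke / control) somatosensory stimulation study:
each participant receives, on each arm and each forearm muscle union, eight
stimulation schemes — five focal vibration intensities (FVS-1..5, 1.9 G down
to 0.7 G) and three electrical-stimulation levels (NMES-1 motor threshold,
NMES-2 median sensory level, NMES-3 perceptual threshold).  A trial is a
4-minute, 62-channel, 1000-Hz recording containing six 10-s stimulation
blocks separated by 25-s quiet gaps.

The signal model is deliberately minimal but sufficient for every pipeline
statistic to be estimable against ground truth:

* pink (1/f) background noise per channel;
* theta/alpha/beta/gamma sinusoidal oscillators with slowly varying,
  unit-mean random envelopes;
* within each stimulation block, alpha/beta envelopes are suppressed by an
  event-related desynchronization factor ``1 - depth * exp(-t/tau)`` on
  sensorimotor channels, split between hemispheres by a laterality weight;
* the theta envelope is amplified over the first 0.5 s of each block
  (onset theta synchronization);
* a positive P300 half-wave of configurable amplitude/latency/width is added
  to midline channels.

Effect magnitudes scale with scheme intensity; the stroke group has
attenuated responses and a laterality shift toward the contralesional
hemisphere.  All randomness derives from a master seed through per-trial
substreams, so any single trial can be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Recording
from .montage import CHANNELS_62, sensorimotor_set

GROUPS = ("stroke", "control")
ARMS = ("dominant", "nondominant")
MUSCLE_UNIONS = ("ECU-ED", "FCR-FD")
SCHEME_LABELS = (
    "FVS-1", "FVS-2", "FVS-3", "FVS-4", "FVS-5",
    "NMES-1", "NMES-2", "NMES-3",
)

#: FVS vibration intensities in G, strongest to weakest.
FVS_INTENSITIES_G = {"FVS-1": 1.9, "FVS-2": 1.6, "FVS-3": 1.3, "FVS-4": 1.0, "FVS-5": 0.7}
#: NMES threshold roles in decreasing effective drive.
NMES_ROLES = {"NMES-1": "motor", "NMES-2": "median", "NMES-3": "perceptual"}

#: Oscillator center frequencies (Hz) per band.
OSC_FREQ = {"theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 40.0}

#: Midline weights for the additive P300 component.
P300_WEIGHTS = {"Fz": 0.8, "Cz": 1.0, "Pz": 0.9, "FC1": 0.4, "FC2": 0.4,
                "CP1": 0.4, "CP2": 0.4, "C1": 0.3, "C2": 0.3}


@dataclass(frozen=True)
class SchemeSpec:
    """One stimulation scheme: type, ordinal intensity, nominal intensity."""

    label: str
    stim_type: str            # "FVS" | "NMES"
    intensity_level: int      # 1..5 (FVS) or 1..3 (NMES); 1 = strongest
    nominal_intensity: object  # G units (FVS) or threshold role (NMES)

    @property
    def drive(self) -> float:
        """Effective stimulation drive in [0, 1], monotone in intensity."""
        if self.stim_type == "FVS":
            return float(self.nominal_intensity) / max(FVS_INTENSITIES_G.values())
        return {"motor": 1.0, "median": 0.7, "perceptual": 0.4}[self.nominal_intensity]


def scheme_spec(label: str) -> SchemeSpec:
    if label in FVS_INTENSITIES_G:
        level = int(label.split("-")[1])
        return SchemeSpec(label, "FVS", level, FVS_INTENSITIES_G[label])
    if label in NMES_ROLES:
        level = int(label.split("-")[1])
        return SchemeSpec(label, "NMES", level, NMES_ROLES[label])
    raise ValueError(f"unknown stimulation scheme {label!r}")


@dataclass
class DesignSpec:
    """Factorial study design: groups x subjects x arms x unions x schemes x blocks."""

    groups: tuple = GROUPS
    subjects_per_group: int = 15
    arms: tuple = ARMS
    muscle_unions: tuple = MUSCLE_UNIONS
    schemes: tuple = SCHEME_LABELS
    blocks_per_trial: int = 6
    analyzed_channels: tuple = CHANNELS_62
    sampling_rate: float = 1000.0
    trial_duration: float = 240.0
    block_duration: float = 10.0
    baseline_duration: float = 5.0
    quiet_gap: float = 25.0       # between consecutive blocks; must be >= 20 s
    first_onset: float = 10.0

    def __post_init__(self):
        self.groups = tuple(self.groups)
        self.arms = tuple(self.arms)
        self.muscle_unions = tuple(self.muscle_unions)
        self.schemes = tuple(self.schemes)
        self.analyzed_channels = tuple(self.analyzed_channels)
        if len(set(self.analyzed_channels)) != len(self.analyzed_channels):
            raise ValueError("duplicate channel labels in analyzed_channels")
        for s in self.schemes:
            scheme_spec(s)  # validates labels

    @property
    def episodes_per_group(self) -> int:
        """Closed-form episode count per group (episode = epoch x channel)."""
        return (
            self.subjects_per_group
            * len(self.arms)
            * len(self.muscle_unions)
            * len(self.schemes)
            * self.blocks_per_trial
            * len(self.analyzed_channels)
        )

    def block_onsets(self) -> np.ndarray:
        """Block onset times (s): fixed schedule, 10 s on + quiet gap."""
        step = self.block_duration + self.quiet_gap
        onsets = self.first_onset + step * np.arange(self.blocks_per_trial)
        last_end = onsets[-1] + self.block_duration
        if self.quiet_gap < 20.0:
            raise ValueError("quiet gap between blocks must be at least 20 s")
        if onsets[0] < self.baseline_duration:
            raise ValueError("first block onset leaves no room for the baseline")
        if last_end > self.trial_duration:
            raise ValueError("block schedule exceeds the trial duration")
        return onsets


@dataclass
class EffectParams:
    """Ground-truth effect parameters injected into one synthetic trial."""

    p300_amp: float = 0.0            # µV
    p300_latency: float = 0.4        # s after onset
    p300_width: float = 0.3          # s (half-wave support)
    theta_ers_gain: float = 1.0      # multiplicative envelope gain, first 0.5 s
    alpha_erd_depth: float = 0.0     # fraction in [0, 1]
    beta_erd_depth: float = 0.0      # fraction in [0, 1]
    erd_adaptation_tau: float = 6.0  # s; ERD recovers toward baseline
    laterality_weight: float = 0.7   # fraction of effect on contralateral hemisphere
    noise_1f_scale: float = 5.0      # µV RMS of pink background
    osc_base_amp: dict = field(default_factory=lambda: {
        "theta": 4.0, "alpha": 6.0, "beta": 3.0, "gamma": 1.5})

    def __post_init__(self):
        if not (0.0 <= self.alpha_erd_depth <= 1.0 and 0.0 <= self.beta_erd_depth <= 1.0):
            raise ValueError("ERD depths must lie in [0, 1]")
        if not (0.25 <= self.p300_latency <= 0.8):
            raise ValueError("p300_latency must lie in [0.25, 0.8] s")
        if min(self.p300_amp, self.p300_width, self.theta_ers_gain,
               self.noise_1f_scale, self.laterality_weight) < 0:
            raise ValueError("amplitudes and weights must be non-negative")


def default_effects(group: str, scheme: SchemeSpec | str,
                    stroke_amp_factor: float = 0.6,
                    stroke_erd_factor: float = 0.6,
                    stroke_laterality: float = 0.35) -> EffectParams:
    """Ground-truth effect parameters for a (group, scheme) cell.

    Encodes the qualitative response structure the pipeline must recover:
    higher intensity -> larger, earlier P300; vibration (FVS) -> earlier and
    (in controls) larger P300 than electrical stimulation (NMES) at matched
    rank; the stroke group has attenuated amplitudes/ERD and a laterality
    weight shifted toward the contralesional hemisphere.
    """
    if isinstance(scheme, str):
        scheme = scheme_spec(scheme)
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    d = scheme.drive
    if scheme.stim_type == "FVS":
        amp = 8.0 * d
        lat = 0.55 - 0.17 * d
    else:
        amp = 7.0 * d
        lat = 0.65 - 0.15 * d
    eff = EffectParams(
        p300_amp=amp,
        p300_latency=lat,
        p300_width=0.30,
        theta_ers_gain=1.0 + 1.5 * d,
        alpha_erd_depth=min(1.0, 0.30 + 0.40 * d),
        beta_erd_depth=min(1.0, 0.25 + 0.30 * d),
    )
    if group == "stroke":
        # FVS P300 attenuation is strong; NMES amplitudes stay comparable.
        amp_f = stroke_amp_factor if scheme.stim_type == "FVS" else 0.95
        eff.p300_amp *= amp_f
        eff.theta_ers_gain = 1.0 + (eff.theta_ers_gain - 1.0) * stroke_erd_factor
        eff.alpha_erd_depth *= stroke_erd_factor
        eff.beta_erd_depth *= stroke_erd_factor
        eff.laterality_weight = stroke_laterality
    return eff


def zero_effects() -> EffectParams:
    """Null configuration: background signal only, no stimulus-locked effect."""
    return EffectParams(p300_amp=0.0, theta_ers_gain=1.0,
                        alpha_erd_depth=0.0, beta_erd_depth=0.0)


# ---------------------------------------------------------------------------
# design enumeration and manifest
# ---------------------------------------------------------------------------

def build_design(config: DesignSpec) -> pd.DataFrame:
    """Flat deterministic episode index, one row per
    group x subject x arm x union x scheme x block x channel.
    """
    config.block_onsets()  # validates schedule
    idx = pd.MultiIndex.from_product(
        [
            config.groups,
            range(1, config.subjects_per_group + 1),
            config.arms,
            config.muscle_unions,
            config.schemes,
            range(config.blocks_per_trial),
            config.analyzed_channels,
        ],
        names=["group", "subject", "arm", "union", "scheme", "block", "channel"],
    )
    return idx.to_frame(index=False)


def _trial_seed(master_seed: int, trial_index: int) -> int:
    # counter-based mixing keeps trial substreams order-independent
    return int((np.uint64(master_seed) * np.uint64(1000003)
                + np.uint64(trial_index)) % np.uint64(2**31))


def arm_side(group: str, arm: str, lesioned_hemisphere: str | None) -> str:
    """Physical side ('left'|'right') of the stimulated arm.

    All participants are right-handed, so the dominant arm is the right arm.
    For stroke participants the 'dominant'/'nondominant' labels still refer
    to handedness; the affected arm is contralateral to the lesion.
    """
    del group, lesioned_hemisphere
    return "right" if arm == "dominant" else "left"


@dataclass
class SimulationManifest:
    """Per-trial ground truth: factorial cell, seed, onsets, effect parameters."""

    master_seed: int
    design: DesignSpec
    trials: pd.DataFrame          # one row per trial
    effects: dict                 # trial_id -> EffectParams

    def to_files(self, path: Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(path / "manifest.csv", index=False)
        side = {tid: asdict(eff) for tid, eff in self.effects.items()}
        (path / "effects.json").write_text(
            json.dumps({"master_seed": self.master_seed, "effects": side}, indent=1))


def build_manifest(design: DesignSpec, master_seed: int,
                   effects_fn=default_effects) -> SimulationManifest:
    """Enumerate all trials of the design and assign seeds + effect params.

    ``effects_fn(group, scheme_spec)`` supplies the ground truth per cell;
    pass ``lambda g, s: zero_effects()`` for a global-null study.
    """
    onsets = design.block_onsets()
    rows = []
    effects = {}
    i = 0
    for group in design.groups:
        for subj in range(1, design.subjects_per_group + 1):
            # alternate lesion side within the stroke group; controls have none
            lesion = (None if group != "stroke"
                      else ("left" if subj % 2 else "right"))
            for arm in design.arms:
                for union in design.muscle_unions:
                    for scheme in design.schemes:
                        tid = f"{group}-s{subj:02d}-{arm}-{union}-{scheme}"
                        eff = effects_fn(group, scheme_spec(scheme))
                        rows.append({
                            "trial_id": tid,
                            "group": group,
                            "subject": subj,
                            "lesioned_hemisphere": lesion,
                            "arm": arm,
                            "union": union,
                            "scheme": scheme,
                            "stim_side": arm_side(group, arm, lesion),
                            "trial_seed": _trial_seed(master_seed, i),
                            "block_onsets": ";".join(f"{t:g}" for t in onsets),
                        })
                        effects[tid] = eff
                        i += 1
    return SimulationManifest(master_seed=master_seed, design=design,
                              trials=pd.DataFrame(rows), effects=effects)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _pink_noise(rng, n_ch, n, rate, rms):
    """1/f-amplitude noise, flat below 1 Hz, scaled to the requested RMS.

    Synthesis runs in single precision: the quantities of interest are tens
    of µV and downstream filters re-enter double precision anyway.
    """
    white = rng.standard_normal((n_ch, n), dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shaping = (1.0 / np.sqrt(np.maximum(freqs, 1.0))).astype(np.complex64)
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=-1).astype(np.float32)
    std = x.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * np.float32(rms)


def _slow_envelope(rng, n_ch, n, rate, mod_depth=0.3, mod_rate=0.5):
    """Unit-mean, non-negative slowly varying random envelope (per channel)."""
    n_knots = max(4, int(np.ceil(n / rate * mod_rate)) + 2)
    knots = rng.standard_normal((n_ch, n_knots))
    tk = np.linspace(0, n - 1, n_knots)
    t = np.arange(n)
    env = np.empty((n_ch, n), dtype=np.float32)
    for c in range(n_ch):
        env[c] = np.interp(t, tk, knots[c])
    env = np.clip(np.float32(1.0) + np.float32(mod_depth) * env,
                  np.float32(0.05), None)
    return env / env.mean(axis=-1, keepdims=True)


def simulate_trial(entry, design: DesignSpec, effects: EffectParams | None = None,
                   master_seed: int | None = None) -> Recording:
    """Synthesize one 4-min stimulation trial as a continuous Recording.

    Parameters
    ----------
    entry : mapping
        One manifest row (dict-like) with at least ``scheme``, ``stim_side``,
        ``trial_seed``, ``block_onsets`` and the factorial metadata.
    design : DesignSpec
    effects : EffectParams
        Ground truth for this trial (required if not resolvable from entry).
    master_seed : int
        Master seed of the study; combined with the trial seed so the trial
        substream is independent of simulation order.
    """
    if hasattr(entry, "to_dict"):
        entry = entry.to_dict()
    eff = effects
    if eff is None:
        raise ValueError("effects parameters are required")
    rate = design.sampling_rate
    n = int(round(design.trial_duration * rate))
    labels = design.analyzed_channels
    n_ch = len(labels)
    if isinstance(entry.get("block_onsets"), str):
        onsets = np.array([float(x) for x in entry["block_onsets"].split(";")])
    else:
        onsets = np.asarray(entry.get("block_onsets", design.block_onsets()), float)
    gaps = np.diff(onsets) - design.block_duration
    if len(onsets) and (np.any(gaps < 20.0 - 1e-9)
                        or onsets[-1] + design.block_duration > design.trial_duration + 1e-9):
        raise ValueError("block onset schedule violates the quiet-gap/duration invariant")

    seed_key = [int(entry.get("trial_seed", 0))]
    if master_seed is not None:
        seed_key = [int(master_seed)] + seed_key
    rng = np.random.default_rng(np.random.SeedSequence(seed_key))

    t = np.arange(n) / rate
    x = _pink_noise(rng, n_ch, n, rate, eff.noise_1f_scale)

    # laterality: split ERD/ERS between hemispheres relative to stimulated arm
    side = entry.get("stim_side", "right")
    contra = "left" if side == "right" else "right"
    ipsi = side
    w_ch = np.zeros(n_ch)
    for lab in sensorimotor_set(contra):
        if lab in labels:
            w_ch[labels.index(lab)] = eff.laterality_weight
    for lab in sensorimotor_set(ipsi):
        if lab in labels:
            w_ch[labels.index(lab)] = 1.0 - eff.laterality_weight

    block_len = int(round(design.block_duration * rate))
    in_block = np.zeros(n, bool)
    erd_shape = np.zeros(n)        # exp(-t/tau) profile inside blocks
    ers_window = np.zeros(n, bool)  # first 0.5 s of each block
    for t0 in onsets:
        i0 = int(round(t0 * rate))
        sl = slice(i0, i0 + block_len)
        in_block[sl] = True
        erd_shape[sl] = np.exp(-(t[sl] - t0) / eff.erd_adaptation_tau)
        ers_window[i0:i0 + int(round(0.5 * rate))] = True

    t32 = t.astype(np.float32)
    for band, f0 in OSC_FREQ.items():
        amp = eff.osc_base_amp.get(band, 0.0)
        if amp == 0.0:
            continue
        phase = rng.uniform(0, 2 * np.pi, size=(n_ch, 1)).astype(np.float32)
        env = _slow_envelope(rng, n_ch, n, rate)
        if band in ("alpha", "beta"):
            depth = eff.alpha_erd_depth if band == "alpha" else eff.beta_erd_depth
            # channel-weighted ERD with exponential recovery (adaptation)
            env *= np.float32(1.0) - np.outer(w_ch * depth, erd_shape).astype(np.float32)
        elif band == "theta" and eff.theta_ers_gain != 1.0:
            gain = (1.0 + (eff.theta_ers_gain - 1.0) * w_ch).astype(np.float32)
            env *= np.where(ers_window, gain[:, None], np.float32(1.0))
        env *= np.sin(np.float32(2 * np.pi * f0) * t32[None, :] + phase)
        env *= np.float32(amp)
        x += env

    if eff.p300_amp > 0:
        wave = np.zeros(n)
        for t0 in onsets:
            c = t0 + eff.p300_latency
            m = np.abs(t - c) < eff.p300_width / 2
            wave[m] += np.cos(np.pi * (t[m] - c) / eff.p300_width) ** 2
        for lab, w in P300_WEIGHTS.items():
            if lab in labels:
                x[labels.index(lab)] += eff.p300_amp * w * wave

    events = [(int(round(t0 * rate)), str(entry.get("scheme", "STIM"))) for t0 in onsets]
    meta = {k: entry.get(k) for k in
            ("trial_id", "group", "subject", "lesioned_hemisphere",
             "arm", "union", "scheme", "stim_side") if k in entry}
    return Recording(samples=x, rate=rate, channel_labels=labels,
                     events=events, meta=meta)


def write_recording(rec: Recording, path, format: str = "brainvision") -> Path:
    """Write a Recording to disk; see :mod:`eegstim.io` for the writers."""
    from . import io as _io
    return _io.write_recording(rec, path, format=format)
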
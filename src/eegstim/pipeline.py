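"""End-to-end orchestration: generate -> ingest -> features -> statistics.

`run_synthetic_study` simulates every trial of a factorial design with known
ground truth, pushes each through the ingest chain (filter, flip, segment,
reject), extracts the P300 and band-wise RSP reading units (block averages
per participant x arm x union x scheme), optionally computes ERD/ERS
topographies for the representative schemes, and runs the statistical
battery.  Every random draw derives from the master seed, so a rerun with
the same configuration reproduces the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as _erp
from . import ingest as _ingest
from . import spectral as _spectral
from . import stats as _stats
from . import synthdata as _synth
from . import timefreq as _timefreq
from .synthdata import DesignSpec, build_design, build_manifest, default_effects


@dataclass
class RunConfig:
    """Serializable configuration for a full synthetic-study run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    master_seed: int = 0
    bands: tuple = ("theta", "alpha", "beta", "gamma")
    period_of_interest: tuple = _spectral.PERIOD_OF_INTEREST
    p300_window: tuple = _erp.P300_WINDOW
    filter_band: tuple = (1.0, 100.0)
    notch_band: tuple = (49.0, 51.0)
    ptp_threshold: float = 200.0
    n_perm: int = 2000
    alpha: float = 0.05
    representative_schemes: tuple = ("FVS-1", "NMES-2")
    do_timefreq: bool = False
    topo_band: str = "alpha"
    topo_window: tuple = (0.0, 10.0)
    topo_stat: str = "mean"       # 'mean' | 'peak'
    tfr_decim: int = 20
    ersp_channels: tuple = ("C3", "C4")
    ersp_freqs: tuple = tuple(float(f) for f in range(4, 41, 2))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = DesignSpec(**d["design"])
        return cls(**d)

    def save(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def summarize_reading_units(features: pd.DataFrame, value_cols=None,
                            keys=("group", "subject", "arm", "union", "scheme"),
                            ) -> pd.DataFrame:
    """Average feature values across repeated blocks -> one reading unit per
    participant x arm x union x scheme cell, with the contributing block count."""
    if value_cols is None:
        value_cols = [c for c in features.columns
                      if c not in keys and c != "block"
                      and pd.api.types.is_numeric_dtype(features[c])]
    keys = [k for k in keys if k in features.columns]
    agg = features.groupby(keys, sort=True)[list(value_cols)].mean().reset_index()
    counts = features.groupby(keys, sort=True).size().rename("n_blocks").reset_index()
    return agg.merge(counts, on=keys)


def _trial_features(epochs, entry, config: RunConfig):
    """P300 feature row + per-block RSP rows for one preprocessed trial."""
    side_eff = epochs[0].meta.get("stim_side_effective", entry.get("stim_side"))
    waves = [_erp.midline_p300(_erp.compute_erp(ep)) for ep in epochs]
    mean_wave = _erp.average_waveforms(waves)
    feat = _erp.extract_p300(mean_wave, window=config.p300_window)
    p300_row = {
        "group": entry["group"], "subject": entry["subject"],
        "arm": entry["arm"], "union": entry["union"], "scheme": entry["scheme"],
        "stim_type": entry["scheme"].split("-")[0],
        "peak_amplitude": feat.peak_amplitude,
        "peak_latency": feat.peak_latency,
        "n_blocks": len(epochs),
    }
    rsp_rows = []
    for band in config.bands:
        per_block = np.stack([
            _spectral.compute_rsp(ep, band, config.period_of_interest)
            for ep in epochs])
        for region in ("whole-brain", "contralateral-sensorimotor"):
            val = _spectral.aggregate_rsp(per_block, epochs[0].channel_labels,
                                          region, stimulated_side=side_eff)
            rsp_rows.append({
                "group": entry["group"], "subject": entry["subject"],
                "arm": entry["arm"], "union": entry["union"],
                "scheme": entry["scheme"],
                "stim_type": entry["scheme"].split("-")[0],
                "band": band, "region": region, "rsp": val,
            })
    return p300_row, rsp_rows


def _trial_topomap(epochs, config: RunConfig):
    """Per-channel ERD/ERS (block-averaged) for one trial."""
    band = _spectral.BANDS[config.topo_band]
    freqs = np.arange(band[0], band[1] + 0.5, 1.0)
    data = np.stack([ep.samples for ep in epochs])  # blocks x ch x time
    power, t_dec, valid = _timefreq.compute_tfr_multi(
        data, epochs[0].rate, epochs[0].time, freqs=freqs,
        decim=config.tfr_decim)
    labels = epochs[0].channel_labels
    vals = np.zeros(len(labels))
    for ci in range(len(labels)):
        per_block = []
        for bi in range(len(epochs)):
            tfr = _timefreq.TFR(power=power[bi, ci], freqs=freqs, times=t_dec,
                                valid=valid, channel=labels[ci])
            ersp = _timefreq.compute_ersp(tfr)
            v, _ = _timefreq.compute_erd_ers(ersp, band, config.topo_window,
                                             stat=config.topo_stat)
            per_block.append(v)
        vals[ci] = np.mean(per_block)
    return dict(zip(labels, vals))


def _trial_ersp_maps(epochs, config: RunConfig):
    """Block-mean ERSP map + significance mask at the representative
    bilateral sensorimotor channels (C3/C4 by default)."""
    labels = epochs[0].channel_labels
    chans = [c for c in config.ersp_channels if c in labels]
    idx = [labels.index(c) for c in chans]
    freqs = np.asarray(config.ersp_freqs, float)
    data = np.stack([ep.samples[idx] for ep in epochs])
    power, t_dec, valid = _timefreq.compute_tfr_multi(
        data, epochs[0].rate, epochs[0].time, freqs=freqs,
        decim=config.tfr_decim)
    maps = {}
    for ci, ch in enumerate(chans):
        ersps = []
        for bi in range(len(epochs)):
            tfr = _timefreq.TFR(power=power[bi, ci], freqs=freqs,
                                times=t_dec, valid=valid, channel=ch)
            ersps.append(_timefreq.compute_ersp(tfr))
        mask = _timefreq.baseline_permutation_mask(
            ersps, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.master_seed + 17)
        mean_map = _timefreq.ERSPMap(
            values=np.mean([e.values for e in ersps], axis=0),
            freqs=freqs, times=t_dec,
            valid=np.logical_and.reduce([e.valid for e in ersps]),
            mask=mask, channel=ch)
        maps[ch] = mean_map
    return maps


def run_synthetic_study(config: RunConfig, out_dir=None, effects_fn=None,
                        progress: bool = False) -> dict:
    """Simulate and analyze a full synthetic study; returns the report bundle.

    The bundle contains the episode index counts, the P300 and RSP feature
    tables (per-block and reading-unit), statistics tables, optional ERD/ERS
    topographies with their group comparison, the simulation manifest, and a
    structured log.  If ``out_dir`` is given, tables and the configuration
    are written there.
    """
    t_start = _time.time()
    log = []
    design = config.design
    effects_fn = effects_fn or default_effects

    index = build_design(design)
    per_group = index.groupby("group").size().to_dict()
    log.append({"stage": "design", "episodes_per_group": per_group})

    manifest = build_manifest(design, config.master_seed, effects_fn=effects_fn)

    p300_rows, rsp_rows = [], []
    topo_rows = []
    ersp_maps = {}
    n_rejected = 0
    for _, entry in manifest.trials.iterrows():
        entry = entry.to_dict()
        eff = manifest.effects[entry["trial_id"]]
        rec = _synth.simulate_trial(entry, design, effects=eff,
                                    master_seed=config.master_seed)
        epochs, rej = _ingest.preprocess_recording(
            rec, lesioned_hemisphere=entry["lesioned_hemisphere"],
            metadata=entry, ptp_threshold=config.ptp_threshold,
            band=config.filter_band, notch=config.notch_band)
        n_rejected += len(rej)
        if not epochs:
            log.append({"stage": "ingest", "trial": entry["trial_id"],
                        "warning": "all epochs rejected"})
            continue
        prow, rrows = _trial_features(epochs, entry, config)
        p300_rows.append(prow)
        rsp_rows.extend(rrows)
        if config.do_timefreq and entry["scheme"] in config.representative_schemes:
            tmap = _trial_topomap(epochs, config)
            topo_rows.append({"group": entry["group"], "subject": entry["subject"],
                              "arm": entry["arm"], "union": entry["union"],
                              "scheme": entry["scheme"], **tmap})
            ersp_maps[entry["trial_id"]] = _trial_ersp_maps(epochs, config)
        if progress:
            print(f"  done {entry['trial_id']}", flush=True)
    log.append({"stage": "features", "n_trials": len(p300_rows),
                "n_epochs_rejected": n_rejected})

    p300 = pd.DataFrame(p300_rows)
    rsp = pd.DataFrame(rsp_rows)
    bundle = {
        "config": config,
        "episode_counts": per_group,
        "manifest": manifest,
        "p300": p300,
        "rsp": rsp,
    }

    # ------------------------------------------------------------------ stats
    stats_tables = {}
    if not p300.empty:
        plan_rows = []
        for grp, sub in p300.groupby("group"):
            unit = sub.groupby(["subject", "stim_type"])[
                ["peak_amplitude", "peak_latency"]].mean().reset_index()
            wide_lat = unit.pivot(index="subject", columns="stim_type",
                                  values="peak_latency")
            wide_amp = unit.pivot(index="subject", columns="stim_type",
                                  values="peak_amplitude")
            if {"FVS", "NMES"} <= set(wide_lat.columns) and len(wide_lat) >= 3:
                from scipy import stats as sps
                for name, wide in (("latency", wide_lat), ("amplitude", wide_amp)):
                    t, p = sps.ttest_rel(wide["FVS"], wide["NMES"])
                    plan_rows.append({
                        "analysis": "paired_t",
                        "comparison": f"{grp}:P300 {name} FVS vs NMES",
                        "statistic": float(t), "p": float(p),
                        "effect_size": _stats.cohens_d(wide["FVS"], wide["NMES"],
                                                       paired=True),
                        "mean_FVS": float(wide["FVS"].mean()),
                        "mean_NMES": float(wide["NMES"].mean()),
                    })
        stats_tables["p300"] = pd.DataFrame(plan_rows)
    if not rsp.empty and rsp["scheme"].nunique() > 1:
        per_band = []
        for band, sub in rsp[rsp.region == "contralateral-sensorimotor"].groupby("band"):
            units = summarize_reading_units(sub, value_cols=["rsp"],
                                            keys=("group", "subject", "scheme"))
            complete = (units.groupby(["group", "subject"])["scheme"].nunique()
                        == sub["scheme"].nunique())
            enough = units.groupby("group")["subject"].nunique().min() >= 3
            if complete.all() and enough:
                try:
                    bat = _stats.parametric_battery(units, dv="rsp",
                                                    within="scheme")
                    bat.insert(0, "band", band)
                    per_band.append(bat)
                except (ValueError, KeyError):
                    pass
        if per_band:
            stats_tables["rsp"] = pd.concat(per_band, ignore_index=True)

    if ersp_maps:
        bundle["ersp_maps"] = ersp_maps
    topo = pd.DataFrame(topo_rows)
    if not topo.empty:
        bundle["topography"] = topo
        subj_counts = topo.groupby("group")["subject"].nunique()
        if topo["group"].nunique() == 2 and subj_counts.min() >= 2:
            labels = tuple(design.analyzed_channels)
            comp = {}
            for scheme, sub in topo.groupby("scheme"):
                per_subj = sub.groupby(["group", "subject"])[list(labels)].mean()
                g = sorted(set(per_subj.index.get_level_values(0)))
                a = per_subj.loc[g[0]]
                b = per_subj.loc[g[1]]
                comp[scheme] = _stats.topo_compare(
                    a, b, n_perm=config.n_perm, alpha=config.alpha,
                    seed=config.master_seed + 1)
            bundle["topo_comparison"] = comp
    bundle["stats"] = stats_tables
    log.append({"stage": "stats", "tables": sorted(stats_tables),
                "wall_time_s": round(_time.time() - t_start, 2)})
    bundle["log"] = log

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.save(out / "config.yaml")
        manifest.to_files(out / "manifest")
        float_fmt = "%.10g"
        p300.to_csv(out / "p300.csv", index=False, float_format=float_fmt)
        rsp.to_csv(out / "rsp.csv", index=False, float_format=float_fmt)
        if not p300.empty:
            summarize_reading_units(p300, value_cols=["peak_amplitude",
                                                      "peak_latency"]).to_csv(
                out / "p300_reading_units.csv", index=False, float_format=float_fmt)
        for name, tab in stats_tables.items():
            tab.to_csv(out / f"stats_{name}.csv", index=False, float_format=float_fmt)
        if not topo.empty:
            topo.to_csv(out / "topography.csv", index=False, float_format=float_fmt)
        if ersp_maps:
            import h5py

            with h5py.File(out / "ersp_maps.h5", "w") as fh:
                for tid, maps in ersp_maps.items():
                    for ch, m in maps.items():
                        g = fh.create_group(f"{tid}/{ch}")
                        g.create_dataset("values", data=m.values)
                        g.create_dataset("mask", data=m.mask)
                        g.create_dataset("valid", data=m.valid)
                        g.create_dataset("freqs", data=m.freqs)
                        g.create_dataset("times", data=m.times)
        with open(out / "log.jsonl", "w") as fh:
            for rec_ in log:
                fh.write(json.dumps(rec_) + "\n")
    return bundle
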
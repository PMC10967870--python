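import numpy as np
import pytest

from eegstim import timefreq
RATE = 500.0


def _epoch_time(n, rate=RATE, baseline=5.0):
    return (np.arange(n) - int(round(baseline * rate))) / rate


class TestComputeTFR:
    def test_pure_tone_peaks_at_its_frequency(self):
        n = int(15 * RATE)
        t = _epoch_time(n)
        x = np.sin(2 * np.pi * 10.0 * t)
        tfr = timefreq.compute_tfr(x, RATE, t, freqs=np.arange(5.0, 16.0),
                                   decim=5)
        profile = tfr.power[:, tfr.valid.all(axis=0)].mean(axis=1)
        assert tfr.freqs[np.argmax(profile)] == 10.0

    def test_amplitude_step_quadruples_power(self):
        n = int(15 * RATE)
        t = _epoch_time(n)
        x = np.sin(2 * np.pi * 20.0 * t) * np.where(t >= 0, 2.0, 1.0)
        tfr = timefreq.compute_tfr(x, RATE, t, freqs=np.array([20.0]), decim=5)
        pre = tfr.power[0, (tfr.times > -4.0) & (tfr.times < -1.0)].mean()
        post = tfr.power[0, (tfr.times > 1.0) & (tfr.times < 9.0)].mean()
        assert post / pre == pytest.approx(4.0, rel=0.10)

    def test_all_zeros_give_zero_power(self):
        n = int(15 * RATE)
        t = _epoch_time(n)
        tfr = timefreq.compute_tfr(np.zeros(n), RATE, t,
                                   freqs=np.arange(5.0, 10.0), decim=10)
        assert np.all(tfr.power == 0)

    def test_rate_too_low_rejected(self):
        t = _epoch_time(1500, rate=100.0)
        with pytest.raises(ValueError, match="too low"):
            timefreq.compute_tfr(np.zeros(1500), 100.0, t,
                                 freqs=np.array([80.0]))

    def test_edge_bins_flagged_invalid(self):
        n = int(15 * RATE)
        t = _epoch_time(n)
        tfr = timefreq.compute_tfr(np.random.default_rng(0).normal(size=n),
                                   RATE, t, freqs=np.array([3.0]), decim=10)
        assert not tfr.valid[0, 0]          # epoch start is contaminated
        assert tfr.valid[0, tfr.valid.shape[1] // 2]


class TestComputeERSP:
    def _tfr(self, rng, n_sec=15, freqs=np.arange(5.0, 11.0)):
        n = int(n_sec * RATE)
        t = _epoch_time(n)
        x = rng.normal(size=n)
        return timefreq.compute_tfr(x, RATE, t, freqs=freqs, decim=10)

    def test_baseline_span_is_z_normalized(self, rng):
        tfr = self._tfr(rng)
        ersp = timefreq.compute_ersp(tfr)
        base = (ersp.times < 0)[None, :] & ersp.valid
        for i in range(len(ersp.freqs)):
            vals = ersp.values[i, base[i]]
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_invariant_under_global_amplitude_scaling(self, rng):
        n = int(15 * RATE)
        t = _epoch_time(n)
        x = rng.normal(size=n)
        e1 = timefreq.compute_ersp(
            timefreq.compute_tfr(x, RATE, t, freqs=np.arange(5.0, 9.0), decim=10))
        e2 = timefreq.compute_ersp(
            timefreq.compute_tfr(3.7 * x, RATE, t, freqs=np.arange(5.0, 9.0),
                                 decim=10))
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-8)

    def test_power_increase_at_one_frequency_yields_positive_ersp(self):
        signs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(15 * RATE)
            t = _epoch_time(n)
            x = rng.normal(size=n)
            x[t >= 0] += np.sqrt(2.0) * np.sin(2 * np.pi * 8.0 * t[t >= 0])
            tfr = timefreq.compute_tfr(x, RATE, t, freqs=np.array([8.0]),
                                       decim=10)
            ersp = timefreq.compute_ersp(tfr)
            block = (ersp.times >= 0.5) & (ersp.times < 9.5) & ersp.valid[0]
            signs.append(ersp.values[0, block].mean() > 0)
        assert all(signs)

    def test_zero_baseline_sd_names_frequency(self):
        n = int(15 * RATE)
        t = _epoch_time(n)
        tfr = timefreq.compute_tfr(np.zeros(n), RATE, t,
                                   freqs=np.array([7.0]), decim=10)
        with pytest.raises(ValueError, match="7"):
            timefreq.compute_ersp(tfr)


class TestBaselinePermutationMask:
    def _ersps(self, rng, n_blocks=6, effect=0.0):
        out = []
        n = int(15 * RATE)
        t = _epoch_time(n)
        for _ in range(n_blocks):
            x = rng.normal(size=n)
            if effect:
                sl = (t >= 0) & (t < 4.0)
                x[sl] += effect * np.sin(2 * np.pi * 10.0 * t[sl])
            tfr = timefreq.compute_tfr(x, RATE, t,
                                       freqs=np.arange(6.0, 15.0), decim=10)
            out.append(timefreq.compute_ersp(tfr))
        return out

    def test_injected_alpha_effect_recovered(self, rng):
        ersps = self._ersps(rng, effect=2.0)
        mask = timefreq.baseline_permutation_mask(ersps, n_perm=500, seed=0)
        freqs = ersps[0].freqs
        times = ersps[0].times
        truth = np.zeros_like(mask)
        fsel = (freqs >= 9.0) & (freqs <= 11.0)
        tsel = (times >= 0.0) & (times < 4.0)
        truth[np.ix_(fsel, tsel)] = True
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union > 0.3

    def test_no_effect_masks_almost_nothing(self, rng):
        ersps = self._ersps(rng, effect=0.0)
        mask = timefreq.baseline_permutation_mask(ersps, n_perm=500, seed=1)
        assert mask.mean() <= 0.05

    def test_tiny_n_perm_rejected(self, rng):
        ersps = self._ersps(rng, n_blocks=2)
        with pytest.raises(ValueError):
            timefreq.baseline_permutation_mask(ersps, n_perm=5)

    def test_bh_rejections_nest_with_alpha(self, rng):
        ersps = self._ersps(rng, effect=1.0)
        m01 = timefreq.baseline_permutation_mask(ersps, n_perm=300, alpha=0.01,
                                                 seed=3)
        m05 = timefreq.baseline_permutation_mask(ersps, n_perm=300, alpha=0.05,
                                                 seed=3)
        assert np.all(m05[m01])  # every 1%-level rejection survives at 5%


def test_stimulation_evokes_theta_ers_and_alpha_beta_erd_at_c3_c4():
    # end-to-end on generator output: the block-mean ERSP at the central
    # electrodes is positive in theta and negative in alpha/beta
    from eegstim import ingest
    from eegstim.synthdata import DesignSpec, default_effects, simulate_trial

    design = DesignSpec()
    eff = default_effects("control", "FVS-1")
    rec = simulate_trial({"scheme": "FVS-1", "trial_seed": 21,
                          "stim_side": "right",
                          "block_onsets": design.block_onsets()},
                         design, effects=eff, master_seed=21)
    rec = ingest.bandpass_notch(rec)
    epochs = ingest.segment_epochs(rec)
    chans = [rec.channel_labels.index(c) for c in ("C3", "C4")]
    data = np.stack([ep.samples[chans] for ep in epochs])
    freqs = np.arange(4.0, 31.0, 2.0)
    power, t_dec, valid = timefreq.compute_tfr_multi(
        data, rec.rate, epochs[0].time, freqs=freqs, decim=20)
    vals = {b: [] for b in ("theta", "alpha", "beta")}
    windows = {"theta": (0.0, 0.5), "alpha": (0.0, 6.0), "beta": (0.0, 6.0)}
    for bi in range(len(epochs)):
        for ci in range(2):
            tfr = timefreq.TFR(power=power[bi, ci], freqs=freqs, times=t_dec,
                               valid=valid)
            ersp = timefreq.compute_ersp(tfr)
            for band in vals:
                v, _ = timefreq.compute_erd_ers(ersp, band, windows[band])
                vals[band].append(v)
    assert np.mean(vals["theta"]) > 0
    assert np.mean(vals["alpha"]) < 0
    assert np.mean(vals["beta"]) < 0


class TestErdErs:
    def _map(self, values, freqs, times):
        return timefreq.ERSPMap(values=values, freqs=freqs, times=times,
                                valid=np.ones_like(values, bool))

    def test_constant_map_returns_constant(self):
        freqs = np.arange(8.0, 12.0)
        times = np.linspace(0, 10, 50)
        m = self._map(np.full((4, 50), -1.5), freqs, times)
        val, k = timefreq.compute_erd_ers(m, "alpha", (0.0, 10.0))
        assert val == pytest.approx(-1.5)

    def test_band_restriction(self):
        freqs = np.arange(6.0, 16.0)
        times = np.linspace(0, 10, 20)
        values = np.zeros((10, 20))
        values[(freqs >= 8) & (freqs < 12), :] = -2.0
        m = self._map(values, freqs, times)
        val, _ = timefreq.compute_erd_ers(m, "alpha", (0.0, 10.0))
        assert val == pytest.approx(-2.0)

    def test_hand_computed_2x2_window(self):
        freqs = np.array([8.0, 9.0])
        times = np.array([0.5, 1.5])
        m = self._map(np.array([[1.0, -1.0], [3.0, 5.0]]), freqs, times)
        val, k = timefreq.compute_erd_ers(m, (8.0, 10.0), (0.0, 2.0))
        assert (val, k) == (2.0, 4)

    def test_matches_naive_double_loop(self, rng):
        freqs = np.arange(4.0, 31.0)
        times = np.linspace(-5, 10, 151)
        values = rng.normal(size=(freqs.size, times.size))
        m = self._map(values, freqs, times)
        band, window = (13.0, 30.0), (1.0, 7.0)
        val, k = timefreq.compute_erd_ers(m, band, window)
        # independent oracle: naive accumulation
        acc, cnt = 0.0, 0
        for i, f in enumerate(freqs):
            for j, t in enumerate(times):
                if band[0] <= f < band[1] and window[0] <= t < window[1]:
                    acc += values[i, j]
                    cnt += 1
        assert k == cnt
        assert val == pytest.approx(acc / cnt, rel=1e-12)

    def test_empty_window_rejected(self):
        m = self._map(np.zeros((2, 2)), np.array([8.0, 9.0]),
                      np.array([0.5, 1.5]))
        with pytest.raises(ValueError, match="empty"):
            timefreq.compute_erd_ers(m, (50.0, 60.0), (0.0, 2.0))
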
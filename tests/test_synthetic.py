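import numpy as np
import pytest

from statecortex.core_io import write_session
from statecortex.synthetic import (SimConfig, UnitGroundTruth,
                                   build_state_schedule, draw_units,
                                   make_waveform, simulate_session,
                                   simulate_spikes, simulate_state_lfp)
from statecortex.spectral import BANDS, band_power, compute_psd

from conftest import small_sim_config


class TestDeterminism:
    def test_same_seed_same_session_bytes(self, tmp_path):
        cfg = small_sim_config(n_spont_stims=1, n_click_trials=2,
                               n_trains_per_freq=1)
        s1, _ = simulate_session(cfg, seed=9)
        s2, _ = simulate_session(cfg, seed=9)
        write_session(s1, tmp_path / "a")
        write_session(s2, tmp_path / "b")
        for name in ["lfp.bin", "spikes.tsv", "waveforms.bin", "units.tsv",
                     "events.tsv"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_different_seed_differs(self):
        cfg = small_sim_config(n_spont_stims=1, n_click_trials=2,
                               n_trains_per_freq=1)
        s1, _ = simulate_session(cfg, seed=1)
        s2, _ = simulate_session(cfg, seed=2)
        assert s1.spikes.n_spikes() != s2.spikes.n_spikes() or not np.allclose(
            s1.lfp.samples, s2.lfp.samples)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"no_such_parameter": 1})


class TestStateLFP:
    def test_pure_sync_slow_power_deeper(self):
        lfp = simulate_state_lfp([(0.0, 30.0, "synchronized")], 32, 1000.0, 3)
        f, psd = compute_psd(lfp.samples, 1000.0)
        deep = band_power(f, psd, (0.0, 4.0))[-4:].mean()
        sup = band_power(f, psd, (0.0, 4.0))[:4].mean()
        assert deep > 2 * sup

    def test_gamma_off_leaves_noise_floor(self):
        cfg = SimConfig(gamma_amp_uv=0.0)
        lfp_d = simulate_state_lfp([(0.0, 30.0, "desynchronized")], 32,
                                   1000.0, 3, cfg)
        lfp_ref = simulate_state_lfp([(0.0, 30.0, "desynchronized")], 32,
                                     1000.0, 3, SimConfig(gamma_amp_uv=0.0,
                                                          slow_amp_uv=0.0))
        f, psd = compute_psd(lfp_d.samples[:4], 1000.0)
        f2, psd2 = compute_psd(lfp_ref.samples[:4], 1000.0)
        bp = band_power(f, psd, BANDS["low_gamma"]).mean()
        bp_ref = band_power(f2, psd2, BANDS["low_gamma"]).mean()
        assert bp == pytest.approx(bp_ref, rel=0.35)

    def test_two_state_schedule_superficial_gamma_ratio(self):
        sched = [(0.0, 20.0, "synchronized"), (20.0, 40.0, "desynchronized")]
        lfp = simulate_state_lfp(sched, 32, 1000.0, 4)
        f_s, p_s = compute_psd(lfp.samples[:4, 2000:18000], 1000.0)
        f_d, p_d = compute_psd(lfp.samples[:4, 22000:38000], 1000.0)
        ratio = (band_power(f_d, p_d, BANDS["low_gamma"]).mean()
                 / band_power(f_s, p_s, BANDS["low_gamma"]).mean())
        assert ratio > 1.0

    def test_empty_schedule_rejected(self):
        with pytest.raises(ValueError, match="empty schedule"):
            simulate_state_lfp([], 32, 1000.0, 0)


def _unit(cfg, **overrides):
    base = dict(
        unit_id=0, area="AC", cell_class="BS2", depth_channel=10,
        relative_depth_um=-100.0, ttp_ms=0.7, quality=30.0,
        rate_sync=5.0, rate_desync=5.0, r_up=8.0, r_down=0.1,
        onset_spikes={"synchronized": 1.5, "desynchronized": 1.0},
        rebound_time_ms={"synchronized": 150.0, "desynchronized": 120.0},
        kappa={"synchronized": {hz: 1.0 for hz in cfg.train_freqs},
               "desynchronized": {hz: 1.0 for hz in cfg.train_freqs}},
        locked_rate=20.0,
    )
    base.update(overrides)
    return UnitGroundTruth(**base)


class TestSimulateSpikes:
    def _ground_truth(self, cfg, session_len, schedule, ups=()):
        from statecortex.synthetic import GroundTruth
        return GroundTruth(state_schedule=schedule, up_intervals=list(ups),
                           units=[], recipient_channel=cfg.recipient_channel,
                           seed=21, config=cfg, session_len_s=session_len)

    def _empty_events(self):
        from conftest import make_events
        return make_events([(1.0, "bf_on", np.nan, np.nan, "b", "stim"),
                            (2.0, "bf_off", np.nan, np.nan, "b", "stim")])

    def test_zero_rates_empty_train(self):
        cfg = SimConfig()
        gt = self._ground_truth(cfg, 50.0, [(0.0, 50.0, "synchronized")])
        u = _unit(cfg, r_up=0.0, r_down=0.0,
                  onset_spikes={"synchronized": 0.0, "desynchronized": 0.0})
        spikes = simulate_spikes(u, gt, self._empty_events(), 21)
        assert spikes.size == 0

    def test_tonic_poisson_count(self):
        """100 s at 10 Hz -> about 1000 spikes (Poisson oracle)."""
        cfg = SimConfig()
        gt = self._ground_truth(cfg, 100.0, [(0.0, 100.0, "desynchronized")])
        u = _unit(cfg, rate_desync=10.0)
        spikes = simulate_spikes(u, gt, self._empty_events(), 21)
        assert abs(spikes.size - 1000) < 3 * np.sqrt(1000)

    def test_high_concentration_phases_tight(self):
        """kappa = 50 on a 64 Hz train concentrates phases near the click."""
        from statecortex.circular import extract_phases
        from conftest import make_events
        cfg = SimConfig()
        onsets = [5.0 + 2.0 * k for k in range(10)]
        rows = []
        for o in onsets:
            rows.append((o, "train_onset", 70.0, 64, "t", "no_stim"))
            rows.append((o + 1.0, "train_offset", np.nan, np.nan, "t",
                         "no_stim"))
        events = make_events(rows)
        gt = self._ground_truth(cfg, 30.0, [(0.0, 30.0, "desynchronized")])
        kap = {hz: 50.0 for hz in cfg.train_freqs}
        u = _unit(cfg, rate_sync=0.0, rate_desync=0.0, r_up=0.0, r_down=0.0,
                  onset_spikes={"synchronized": 0.0, "desynchronized": 0.0},
                  kappa={"synchronized": kap, "desynchronized": kap},
                  locked_rate=64.0)
        spikes = simulate_spikes(u, gt, events, 21)
        ps = extract_phases(spikes, onsets, 64)
        wrapped = np.minimum(ps.phases, 2 * np.pi - ps.phases)
        assert ps.n > 100
        assert np.all(wrapped < 0.75)
        assert np.quantile(wrapped, 0.95) < 0.3

    def test_strictly_increasing(self):
        cfg = SimConfig()
        gt = self._ground_truth(cfg, 50.0, [(0.0, 50.0, "desynchronized")])
        u = _unit(cfg, rate_desync=40.0)
        spikes = simulate_spikes(u, gt, self._empty_events(), 21)
        assert np.all(np.diff(spikes) > 0)


class TestWaveforms:
    def test_constructed_width_exact_on_grid(self):
        from statecortex.unit_classes import trough_to_peak
        wf = make_waveform(0.30, 7, 16, 20000.0, 64)
        assert trough_to_peak(wf[7], 20000.0) == pytest.approx(0.30, abs=0.05)

    def test_amplitude_peaks_on_depth_channel(self):
        from statecortex.laminar import estimate_unit_depth
        for ch in [0, 5, 15]:
            wf = make_waveform(0.7, ch, 16, 20000.0, 64)
            assert estimate_unit_depth(wf) == ch

    def test_small_noise_keeps_classification(self):
        """Classification of each simulated unit is identical with and
        without waveform noise at the default SD."""
        from statecortex.laminar import estimate_unit_depth
        from statecortex.unit_classes import classify_unit, trough_to_peak
        cfg = SimConfig()
        rng = np.random.default_rng(31)
        for gt in draw_units(cfg, seed=5)[:20]:
            clean = make_waveform(gt.ttp_ms, gt.depth_channel, cfg.n_channels,
                                  cfg.wave_fs, cfg.n_wave_samples)
            noisy = make_waveform(gt.ttp_ms, gt.depth_channel, cfg.n_channels,
                                  cfg.wave_fs, cfg.n_wave_samples,
                                  noise_uv=cfg.wave_noise_uv, rng=rng)
            for wf in (clean, noisy):
                ch = estimate_unit_depth(wf)
                cls = classify_unit(
                    trough_to_peak(wf[ch], cfg.wave_fs),
                    (cfg.recipient_channel - ch) * cfg.spacing_um,
                    "MGB" if gt.area == "MGB" else "AC")
                assert cls == gt.cell_class

    def test_depth_channel_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            make_waveform(0.7, 40, 16, 20000.0, 64)


class TestNullSimulation:
    def test_identical_state_parameters_give_zero_band_mi(self):
        """With sync parameters equal to desync parameters the band-power
        modulation indices vanish (averaged over channels)."""
        from statecortex.pipeline import (spontaneous_state_epochs, _segments)
        from statecortex.spectral import (band_power_state_mi,
                                          band_power_table, preprocess_lfp)
        # many short stimulation repetitions: the 3 s windows give few
        # independent delta cycles each, so the MI tolerance needs ~25
        # window pairs of spectral averaging
        cfg = small_sim_config(
            slow_desync_factor=1.0, gamma_sync_factor=1.0,
            n_spont_stims=24, spont_period_s=8.0,
            n_click_trials=2, n_trains_per_freq=1,
        )
        session, _ = simulate_session(cfg, seed=17)
        lfp = preprocess_lfp(session.lfp)
        ep = spontaneous_state_epochs(session, 3.0, 10.0)
        table = band_power_table({
            "synchronized": _segments(lfp, ep.intervals("synchronized")),
            "desynchronized": _segments(lfp, ep.intervals("desynchronized")),
        }, lfp.fs)
        mi = band_power_state_mi(table)
        for band, g in mi.groupby("band"):
            assert abs(g["mi"].mean()) < 0.05


class TestGroundTruthDirections:
    def test_default_config_bs1_rate_ratio_below_one(self):
        units = draw_units(SimConfig(), seed=7)
        for gt in units:
            if gt.cell_class in ("BS1", "BS4"):
                assert gt.rate_desync / gt.rate_sync < 1.0

    def test_schedule_covers_session_without_gaps(self):
        cfg = small_sim_config()
        _, gt = simulate_session(cfg, seed=2)
        sched = sorted(gt.state_schedule)
        assert sched[0][0] == 0.0
        for (a0, a1, _), (b0, b1, _) in zip(sched, sched[1:]):
            assert b0 == pytest.approx(a1)
        assert sched[-1][1] == pytest.approx(gt.session_len_s)
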
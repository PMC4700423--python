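import numpy as np
import pandas as pd
import pytest

from statecortex.core_io import LaminarLFP
from statecortex.spectral import (BANDS, band_power, band_power_state_mi,
                                  band_power_table, compute_psd,
                                  preprocess_lfp, state_index)


def sine_lfp(freq, fs, dur=4.0, n_ch=3, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return LaminarLFP(samples=np.tile(x, (n_ch, 1)), fs=fs)


class TestPreprocess:
    def test_passband_sine_preserved(self):
        raw = sine_lfp(10.0, 20000.0)
        out = preprocess_lfp(raw)
        assert out.fs == 1000.0
        assert out.n_samples == round(raw.n_samples * 1000 / 20000)
        # amplitude within 1% away from resampling edges
        mid = out.samples[0, 500:-500]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_stopband_sine_attenuated(self):
        raw = sine_lfp(400.0, 20000.0)
        out = preprocess_lfp(raw)
        rms_in = np.sqrt(np.mean(raw.samples[0] ** 2))
        rms_out = np.sqrt(np.mean(out.samples[0, 500:-500] ** 2))
        assert 20 * np.log10(rms_in / rms_out) > 20.0

    def test_already_1khz_not_resampled(self):
        raw = sine_lfp(10.0, 1000.0)
        out = preprocess_lfp(raw)
        assert out.fs == 1000.0 and out.n_samples == raw.n_samples

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="sampling theorem"):
            preprocess_lfp(sine_lfp(10.0, 350.0))


class TestPSD:
    @pytest.mark.parametrize("method", ["multitaper", "welch"])
    def test_sine_peak_frequency(self, method):
        rng = np.random.default_rng(0)
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 40 * t) + 0.1 * rng.standard_normal(t.size)
        freqs, psd = compute_psd(x, fs, method=method)
        assert freqs[np.argmax(psd[0])] == pytest.approx(40.0, abs=1.5)

    def test_zero_signal_gives_zero_psd(self):
        freqs, psd = compute_psd(np.zeros(2000), 1000.0)
        assert np.all(psd == 0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            compute_psd(np.zeros(500), 1000.0)

    @pytest.mark.parametrize("method", ["multitaper", "welch"])
    def test_disjoint_noise_segments_agree(self, method):
        rng = np.random.default_rng(1)
        fs = 1000.0
        x = rng.standard_normal(int(20 * fs))
        _, p1 = compute_psd(x[:10000], fs, method=method)
        _, p2 = compute_psd(x[10000:], fs, method=method)
        # no systematic offset between estimates of the same flat spectrum
        assert np.mean(p1) == pytest.approx(np.mean(p2), rel=0.1)

    @pytest.mark.parametrize("method", ["multitaper", "welch"])
    def test_parseval_total_power(self, method):
        """Total band power approximates the signal variance."""
        rng = np.random.default_rng(2)
        fs = 1000.0
        x = rng.standard_normal(int(30 * fs))
        freqs, psd = compute_psd(x, fs, method=method, fmax=fs / 2)
        total = band_power(freqs, psd, (0.0, fs / 2))[0]
        assert total == pytest.approx(np.var(x), rel=0.05)


class TestBandPower:
    def test_constant_psd_rectangle(self):
        freqs = np.linspace(0, 100, 401)
        psd = np.full((1, freqs.size), 2.5)
        assert band_power(freqs, psd, (0, 4))[0] == pytest.approx(10.0)

    def test_band_additivity(self):
        rng = np.random.default_rng(3)
        freqs = np.linspace(0, 100, 401)
        psd = rng.uniform(0, 1, (1, freqs.size))
        parts = sum(band_power(freqs, psd, b)[0] for b in BANDS.values())
        total = band_power(freqs, psd, (0.0, 50.0))[0]
        assert parts == pytest.approx(total)

    def test_sine_power_lands_in_its_band(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 40 * t)
        freqs, psd = compute_psd(x, fs)
        low_gamma = band_power(freqs, psd, BANDS["low_gamma"])[0]
        delta = band_power(freqs, psd, BANDS["delta"])[0]
        assert low_gamma > 10 * max(delta, 1e-12)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="empty band"):
            band_power(np.linspace(0, 100, 101), np.zeros((1, 101)), (10, 10))


class TestBandPowerMI:
    def test_equal_states_give_zero_mi(self):
        rng = np.random.default_rng(4)
        seg = rng.standard_normal((3, 3000))
        table = band_power_table(
            {"synchronized": [seg], "desynchronized": [seg]}, 1000.0)
        mi = band_power_state_mi(table)
        assert np.allclose(mi["mi"], 0.0)

    def test_bounds_when_one_state_silent(self):
        rows = [
            {"channel": 0, "band": "delta", "state": "synchronized", "power": 5.0},
            {"channel": 0, "band": "delta", "state": "desynchronized", "power": 0.0},
        ]
        mi = band_power_state_mi(pd.DataFrame(rows))
        assert mi["mi"].iloc[0] == -1.0

    def test_simulated_state_directions(self, small_session):
        """Deep delta power falls and superficial low-gamma power rises
        after BF stimulation in the generated sessions."""
        from statecortex.pipeline import (spontaneous_state_epochs, _segments)
        from statecortex.spectral import preprocess_lfp
        session, gt = small_session
        lfp = preprocess_lfp(session.lfp)
        ep = spontaneous_state_epochs(session, 3.0, 10.0)
        table = band_power_table({
            "synchronized": _segments(lfp, ep.intervals("synchronized")),
            "desynchronized": _segments(lfp, ep.intervals("desynchronized")),
        }, lfp.fs)
        mi = band_power_state_mi(table).set_index(["channel", "band"])
        rc = gt.recipient_channel
        deep = [c for c in range(lfp.n_channels) if c >= rc + 6]
        sup = [c for c in range(lfp.n_channels) if c <= rc]
        assert np.mean([mi.loc[(c, "delta"), "mi"] for c in deep]) < 0
        assert np.mean([mi.loc[(c, "low_gamma"), "mi"] for c in sup]) > 0


class TestStateIndex:
    def test_zero_signal_gives_zeros(self):
        lfp = LaminarLFP(samples=np.zeros((3, 20000)), fs=1000.0)
        _, p = state_index(lfp, channel=2)
        assert np.all(p == 0)

    def test_stationary_noise_flat(self):
        rng = np.random.default_rng(5)
        lfp = LaminarLFP(samples=rng.standard_normal((3, 60000)), fs=1000.0)
        _, p = state_index(lfp, channel=2)
        assert p.std() / p.mean() < 0.5

    def test_window_longer_than_signal_rejected(self):
        lfp = LaminarLFP(samples=np.zeros((3, 1500)), fs=1000.0)
        with pytest.raises(ValueError, match="longer than signal"):
            state_index(lfp, channel=0, window_s=2.0)

    def test_index_drops_during_desynchronization(self, small_session):
        session, gt = small_session
        from statecortex.spectral import preprocess_lfp
        lfp = preprocess_lfp(session.lfp)
        t, p = state_index(lfp, channel=min(lfp.n_channels - 1,
                                            gt.recipient_channel + 8))
        desync = np.zeros(t.size, bool)
        for a, b, lab in gt.state_schedule:
            if lab == "desynchronized":
                desync |= (t >= a + 1) & (t < b - 1)
        sync_median = np.median(p[~desync])
        assert np.median(p[desync]) < 0.5 * sync_median
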
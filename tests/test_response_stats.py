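import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statecortex.response_stats import (NormalizedPSTH, TrialCounts,
                                        correlation_matrix, count_in_windows,
                                        fano, mean_spike_time,
                                        modulation_index, normalized_psth,
                                        responsive_filter,
                                        spike_count_correlation, trial_counts,
                                        up_vs_desync_index)


class TestModulationIndex:
    @pytest.mark.parametrize("sync,desync,expected", [
        (2.0, 6.0, 0.5),
        (3.0, 3.0, 0.0),
        (5.0, 0.0, -1.0),
        (0.0, 5.0, 1.0),
    ])
    def test_examples(self, sync, desync, expected):
        assert modulation_index(sync, desync) == pytest.approx(expected)

    def test_both_zero_is_missing_not_zero(self):
        assert np.isnan(modulation_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(-1.0, 2.0)

    @settings(max_examples=200, derandomize=True)
    @given(a=st.floats(0, 1e6), b=st.floats(0, 1e6))
    def test_bounded_and_antisymmetric(self, a, b):
        if a + b == 0:
            return
        mi = modulation_index(a, b)
        assert -1.0 <= mi <= 1.0
        assert modulation_index(b, a) == pytest.approx(-mi, abs=1e-12)

    def test_up_variant_orientation(self):
        # UP firing above desynchronized firing gives a positive index
        assert up_vs_desync_index(6.0, 2.0) == pytest.approx(0.5)


class TestTrialCounts:
    def test_window_is_half_open(self):
        spikes = np.array([1.0, 1.099, 1.100])
        counts = count_in_windows(spikes, [1.0], (0.0, 100.0))
        assert counts[0] == 2  # spike at exactly +100 ms excluded

    def test_empty_train_gives_zero_counts(self):
        tc = trial_counts(np.array([]), {"synchronized": [1.0, 2.0]})
        assert tc["synchronized"].counts.tolist() == [0, 0]

    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(0)
        onsets = np.arange(1000) * 1.0
        spikes = np.sort(np.concatenate([
            o + rng.uniform(0, 0.1, rng.poisson(5)) for o in onsets]))
        tc = trial_counts(spikes, {"synchronized": onsets})
        # rate 50 Hz over 100 ms -> mean 5, SE sqrt(5/1000)
        assert tc["synchronized"].mean == pytest.approx(5.0, abs=4 * 0.0707)

    def test_no_events_in_state_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            trial_counts(np.array([1.0]), {"synchronized": []})


class TestFano:
    def test_constant_counts_zero(self):
        assert fano([3, 3, 3, 3]) == 0.0

    def test_hand_computed_value(self):
        # counts (0, 2): mean 1, unbiased variance 2 -> Fano 2
        assert fano([0, 2]) == pytest.approx(2.0)

    def test_poisson_fano_near_one(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, 1000)
        assert 0.9 <= fano(counts) <= 1.1

    def test_zero_mean_is_missing(self):
        assert np.isnan(fano([0, 0, 0]))


class TestResponsiveFilter:
    def _counts(self, per_state):
        return {s: TrialCounts(unit_id=0, state=s, counts=c)
                for s, c in per_state.items()}

    def test_silent_in_one_state_excluded(self):
        by_unit = {
            0: self._counts({"synchronized": [1, 0], "desynchronized": [0, 0]}),
            1: self._counts({"synchronized": [1, 0], "desynchronized": [0, 1]}),
        }
        assert responsive_filter(by_unit) == [1]

    def test_all_silent_empty(self):
        by_unit = {0: self._counts({"synchronized": [0], "desynchronized": [0]})}
        assert responsive_filter(by_unit) == []


class TestMeanSpikeTime:
    def test_two_spikes_average(self):
        spikes = np.array([1.100, 1.150])
        assert mean_spike_time(spikes, [1.0]) == pytest.approx(125.0)

    def test_uniform_spikes_centered(self):
        rng = np.random.default_rng(2)
        onsets = np.arange(200) * 1.0
        spikes = np.sort(np.concatenate(
            [o + rng.uniform(0.08, 0.2, 5) for o in onsets]))
        assert mean_spike_time(spikes, onsets) == pytest.approx(140.0, abs=3.0)

    def test_window_boundaries(self):
        spikes = np.array([1.0799, 1.080, 1.1999, 1.200])
        # [80, 200) ms half-open: 80 and 199.9 in, 79.9 and 200 out
        assert mean_spike_time(spikes, [1.0]) == pytest.approx(
            (80.0 + 199.9) / 2)

    def test_no_spikes_missing(self):
        assert np.isnan(mean_spike_time(np.array([]), [1.0]))


class TestNormalizedPSTH:
    def _spikes(self, onsets, offsets_ms):
        return np.sort(np.concatenate(
            [np.asarray(onsets) + ms * 1e-3 for ms in offsets_ms]))

    def test_peak_normalized_to_one(self):
        onsets = np.arange(20) * 1.0
        p = normalized_psth(self._spikes(onsets, [20.0, 21.0]), onsets)
        assert p.profile.max() == pytest.approx(1.0)

    def test_delta_response_peak_latency(self):
        onsets = np.arange(50) * 1.0
        p = normalized_psth(self._spikes(onsets, [20.0]), onsets)
        assert p.peak_latency_ms == pytest.approx(20.0, abs=5.0)

    def test_scale_invariance(self):
        onsets = np.arange(30) * 1.0
        sp1 = self._spikes(onsets, [15.0, 60.0])
        sp2 = self._spikes(onsets, [15.0, 15.5, 60.0, 60.5])  # ~doubled
        p1 = normalized_psth(sp1, onsets)
        p2 = normalized_psth(sp2, onsets)
        assert p1.peak_latency_ms == pytest.approx(p2.peak_latency_ms, abs=1.0)

    def test_no_spikes_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalized_psth(np.array([]), [1.0])


class TestSpikeCountCorrelation:
    def test_identical_trains_r_one(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 3, 40))
        assert spike_count_correlation(t, t, [(0.0, 3.0)]) == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(4)
        windows = [(3.0 * k, 3.0 * k + 3.0) for k in range(20)]  # 60 s total
        a = np.sort(rng.uniform(0, 60, 600))
        b = np.sort(rng.uniform(0, 60, 600))
        assert abs(spike_count_correlation(a, b, windows)) < 0.05

    def test_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0, 3, 50))
        b = np.sort(rng.uniform(0, 3, 50))
        w = [(0.0, 3.0)]
        r_ab = spike_count_correlation(a, b, w)
        r_ba = spike_count_correlation(b, a, w)
        assert r_ab == pytest.approx(r_ba)
        shift = 5.0
        r_shift = spike_count_correlation(a + shift, b + shift,
                                          [(shift, shift + 3.0)])
        assert r_shift == pytest.approx(r_ab, abs=1e-9)

    def test_zero_variance_missing(self):
        a = np.sort(np.random.default_rng(6).uniform(0, 3, 20))
        assert np.isnan(spike_count_correlation(a, np.array([]), [(0.0, 3.0)]))

    def test_common_input_raises_correlation(self):
        """Shared rate fluctuations induce positive correlations, absent
        for independent trains."""
        rng = np.random.default_rng(7)
        windows = [(3.0 * k, 3.0 * k + 3.0) for k in range(10)]
        # shared slow on/off gating (UP/DOWN-like)
        gate = lambda t: (np.sin(2 * np.pi * 1.5 * t) > 0)
        def train():
            cand = np.sort(rng.uniform(0, 30, 600))
            return cand[gate(cand) & (rng.random(cand.size) < 0.8)]
        r_common = spike_count_correlation(train(), train(), windows)
        a = np.sort(rng.uniform(0, 30, 300))
        b = np.sort(rng.uniform(0, 30, 300))
        r_indep = spike_count_correlation(a, b, windows)
        assert r_common > 0.1 > abs(r_indep)

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(8)
        trains = {u: np.sort(rng.uniform(0, 6, 80)) for u in range(3)}
        w = [(0.0, 3.0), (3.0, 6.0)]
        mat = correlation_matrix(trains, w)
        for row in mat.itertuples(index=False):
            direct = spike_count_correlation(
                trains[row.unit_i], trains[row.unit_j], w)
            assert row.r == pytest.approx(direct, abs=1e-9)
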
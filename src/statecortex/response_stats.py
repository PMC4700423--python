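"""Evoked and spontaneous spike-train statistics.

State comparisons use the bounded modulation index
``MI = (DESYNC - SYNC) / (DESYNC + SYNC)`` (an UP-state variant
``(UP - DESYNC)/(UP + DESYNC)`` is also provided).  Evoked onset reliability
is quantified per unit and state from trial spike counts in the first 100 ms
after stimulus onset: mean count mu, variance sigma^2 (n-1 denominator) and
Fano factor sigma^2/mu.  The late response is summarized by the mean spike
time in an 80-200 ms window, pooled over spikes of all trials.  Pairwise
spike-count correlations bin two trains at 1 ms, smooth each with a 5 ms
Gaussian kernel within each analysis window, concatenate windows and take
the Pearson correlation.

All windows are half-open [a, b); times are relative to event onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

ONSET_WINDOW_MS = (0.0, 100.0)
LATE_WINDOW_MS = (80.0, 200.0)
PSTH_WINDOW_MS = (-50.0, 300.0)
PSTH_BIN_MS = 1.0
PSTH_SMOOTH_SD_MS = 5.0
CORR_BIN_MS = 1.0
CORR_SMOOTH_SD_MS = 5.0


def modulation_index(sync_value: float, desync_value: float) -> float:
    """(DESYNC - SYNC) / (DESYNC + SYNC), bounded in [-1, 1].

    Both inputs must be non-negative and not both zero; the both-zero case is
    undefined and returns NaN (the unit is excluded, never counted as 0).
    """
    a, b = float(sync_value), float(desync_value)
    if a < 0 or b < 0:
        raise ValueError("modulation index requires non-negative inputs")
    if a + b == 0:
        return float("nan")
    return (b - a) / (b + a)


def up_vs_desync_index(up_value: float, desync_value: float) -> float:
    """(UP - DESYNC) / (UP + DESYNC): firing in UP states vs desynchronized."""
    return modulation_index(desync_value, up_value)


@dataclass
class TrialCounts:
    """Per-trial spike counts of one unit in one state."""

    unit_id: int
    state: str
    counts: np.ndarray
    window_ms: tuple[float, float] = ONSET_WINDOW_MS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("negative spike count")

    @property
    def n_trials(self) -> int:
        return self.counts.size

    @property
    def mean(self) -> float:
        return float(self.counts.mean()) if self.counts.size else float("nan")

    @property
    def variance(self) -> float:
        if self.counts.size < 2:
            return float("nan")
        return float(self.counts.var(ddof=1))

    @property
    def fano(self) -> float:
        return fano(self.counts)


def count_in_windows(
    spike_times: np.ndarray, onsets: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    """Spike count of one train in [onset + a, onset + b) for each onset."""
    t = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    lo = onsets + window_ms[0] * 1e-3
    hi = onsets + window_ms[1] * 1e-3
    return np.searchsorted(t, hi) - np.searchsorted(t, lo)


def trial_counts(
    spike_times: np.ndarray,
    onsets_by_state: dict[str, np.ndarray],
    window_ms: tuple[float, float] = ONSET_WINDOW_MS,
    unit_id: int = -1,
) -> dict[str, TrialCounts]:
    """Per-trial spike counts per state, from state-labelled event onsets."""
    out = {}
    for state, onsets in onsets_by_state.items():
        onsets = np.asarray(onsets, dtype=float)
        if onsets.size == 0:
            raise ValueError(f"no events in state {state!r}")
        out[state] = TrialCounts(
            unit_id=unit_id, state=state,
            counts=count_in_windows(spike_times, onsets, window_ms),
            window_ms=window_ms,
        )
    return out


def fano(counts: np.ndarray) -> float:
    """Fano factor sigma^2 / mu with unbiased (n-1) variance.

    NaN when the mean count is zero (undefined, unit excluded).
    """
    c = np.asarray(counts, dtype=float)
    mu = c.mean()
    if mu == 0:
        return float("nan")
    return float(c.var(ddof=1) / mu)


def responsive_filter(
    counts_by_unit: dict[int, dict[str, TrialCounts]]
) -> list[int]:
    """Units with at least one onset-window spike in every state separately."""
    kept = []
    for unit_id, per_state in counts_by_unit.items():
        if per_state and all(tc.counts.sum() > 0 for tc in per_state.values()):
            kept.append(unit_id)
    return kept


def mean_spike_time(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    window_ms: tuple[float, float] = LATE_WINDOW_MS,
) -> float:
    """Mean spike time (ms from onset) pooled over spikes of all trials.

    Only spikes with onset-relative time in [window_ms[0], window_ms[1]) are
    pooled; NaN when no spike falls in the window.
    """
    t = np.asarray(spike_times, dtype=float)
    rel_all = []
    for onset in np.asarray(onsets, dtype=float):
        rel = (t[(t >= onset + window_ms[0] * 1e-3)
                 & (t < onset + window_ms[1] * 1e-3)] - onset) * 1e3
        rel_all.append(rel)
    pooled = np.concatenate(rel_all) if rel_all else np.empty(0)
    if pooled.size == 0:
        return float("nan")
    return float(pooled.mean())


def _smooth_gaussian(x: np.ndarray, sd_bins: float) -> np.ndarray:
    # truncate at 4 SD, matching the spike-train smoothing elsewhere
    return ndimage.gaussian_filter1d(x, sd_bins, mode="constant", truncate=4.0)


@dataclass
class NormalizedPSTH:
    """Peak-normalized peristimulus time histogram of one unit/state."""

    unit_id: int
    state: str
    bin_centers_ms: np.ndarray
    profile: np.ndarray  # in [0, 1], max exactly 1
    peak_latency_ms: float


def normalized_psth(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    state: str = "",
    unit_id: int = -1,
    window_ms: tuple[float, float] = PSTH_WINDOW_MS,
    bin_ms: float = PSTH_BIN_MS,
    smooth_sd_ms: float = PSTH_SMOOTH_SD_MS,
) -> NormalizedPSTH:
    """PSTH (1 ms bins, 5 ms Gaussian smoothing) divided by its peak.

    Also records the peak latency (ms from onset) used to sort population
    displays.  Raises ``ValueError`` when the unit has no evoked spike.
    """
    onsets = np.asarray(onsets, dtype=float)
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms, bin_ms)
    hist = np.zeros(edges.size - 1)
    t = np.asarray(spike_times, dtype=float)
    for onset in onsets:
        rel = (t[(t >= onset + window_ms[0] * 1e-3)
                 & (t < onset + window_ms[1] * 1e-3)] - onset) * 1e3
        hist += np.histogram(rel, bins=edges)[0]
    smoothed = _smooth_gaussian(hist, smooth_sd_ms / bin_ms)
    peak = smoothed.max()
    if peak <= 0:
        raise ValueError("all-zero PSTH: no evoked spikes")
    centers = (edges[:-1] + edges[1:]) / 2.0
    profile = smoothed / peak
    return NormalizedPSTH(
        unit_id=unit_id, state=state, bin_centers_ms=centers, profile=profile,
        peak_latency_ms=float(centers[int(np.argmax(smoothed))]),
    )


def binned_smoothed_rates(
    spike_times: np.ndarray,
    windows: list[tuple[float, float]],
    bin_ms: float = CORR_BIN_MS,
    smooth_sd_ms: float = CORR_SMOOTH_SD_MS,
) -> np.ndarray:
    """Bin a train at 1 ms inside each window, smooth within-window, concatenate.

    Smoothing is applied per window so no activity leaks across the
    concatenation joints.
    """
    parts = []
    t = np.asarray(spike_times, dtype=float)
    dt = bin_ms * 1e-3
    for w0, w1 in windows:
        n_bins = int(round((w1 - w0) / dt))
        edges = w0 + np.arange(n_bins + 1) * dt
        counts = np.histogram(t, bins=edges)[0].astype(float)
        parts.append(_smooth_gaussian(counts, smooth_sd_ms / bin_ms))
    if not parts:
        return np.empty(0)
    return np.concatenate(parts)


def spike_count_correlation(
    spikes_i: np.ndarray,
    spikes_j: np.ndarray,
    windows: list[tuple[float, float]],
    bin_ms: float = CORR_BIN_MS,
    kernel_ms: float = CORR_SMOOTH_SD_MS,
) -> float:
    """Pearson correlation of two smoothed binned spike trains.

    NaN when either smoothed vector has zero variance (e.g. an empty train).
    """
    x = binned_smoothed_rates(spikes_i, windows, bin_ms, kernel_ms)
    y = binned_smoothed_rates(spikes_j, windows, bin_ms, kernel_ms)
    if x.size == 0 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def correlation_matrix(
    trains: dict[int, np.ndarray],
    windows: list[tuple[float, float]],
    bin_ms: float = CORR_BIN_MS,
    kernel_ms: float = CORR_SMOOTH_SD_MS,
) -> pd.DataFrame:
    """All-pairs Pearson correlations over concatenated smoothed windows.

    Vectorized equivalent of calling :func:`spike_count_correlation` on every
    unit pair; rows are (unit_i, unit_j, r) for i < j, r NaN for
    zero-variance units.
    """
    ids = sorted(trains)
    mat = np.vstack([
        binned_smoothed_rates(trains[u], windows, bin_ms, kernel_ms)
        for u in ids
    ])
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    rows = []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            val = r[a, b] if sd[a] > 0 and sd[b] > 0 else float("nan")
            rows.append({"unit_i": ids[a], "unit_j": ids[b], "r": val})
    return pd.DataFrame(rows)
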
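"""Cortical state segmentation: UP-state detection and BF-stimulation epochs.

UP states are detected from smoothed multiunit activity (MUA): the summed
spike counts of all cortical units in 1 ms bins, convolved with a 10 ms-SD
Gaussian kernel.  The detection threshold is the geometric mean of the
smoothed MUA over all spontaneous (stimulus-free) bins.  An UP-state onset
is a bin where the MUA crosses above threshold, preceded by at least 100 ms
in which the mean MUA stayed below 20% of threshold; onsets are retained
only when the MUA remains above threshold throughout the following 200 ms,
and each retained UP state is reported as that 200 ms window (the window
used for UP-state firing-rate estimates).

Synchronized / desynchronized epochs come from the BF-stimulation event
table: for spontaneous analyses, 3 s windows immediately before stimulation
onset (synchronized) and after stimulation offset (desynchronized); for
evoked analyses, trials in stimulation blocks are desynchronized and trials
in no-stimulation blocks synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import EventTable, SpikeTrainSet, StateEpochs

MUA_BIN_MS = 1.0
MUA_KERNEL_SD_MS = 10.0
KERNEL_TRUNC_SD = 4.0
PRE_WINDOW_MS = 100.0
PRE_FRACTION = 0.2
UP_WINDOW_MS = 200.0
SPONT_WINDOW_S = 3.0
DESYNC_LEN_S = 10.0


@dataclass
class SmoothedMUA:
    """Smoothed population rate in spikes per bin (1 ms bins)."""

    values: np.ndarray
    bin_s: float
    t0: float
    kernel_sd_ms: float = MUA_KERNEL_SD_MS
    n_units: int = 0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + (np.arange(self.values.size) + 0.5) * self.bin_s

    def kernel_peak(self) -> float:
        """Peak contribution of a single spike to the smoothed series."""
        return 1.0 / (np.sqrt(2 * np.pi) * (self.kernel_sd_ms / (self.bin_s * 1e3)))


def gaussian_kernel(sd_bins: float, trunc_sd: float = KERNEL_TRUNC_SD) -> np.ndarray:
    """Unit-area Gaussian kernel truncated at +/- ``trunc_sd`` SD."""
    half = int(np.ceil(trunc_sd * sd_bins))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    return k / k.sum()


def compute_mua(
    spikes: SpikeTrainSet,
    unit_ids: list[int] | None = None,
    t_start: float = 0.0,
    t_end: float | None = None,
    bin_ms: float = MUA_BIN_MS,
    kernel_ms: float = MUA_KERNEL_SD_MS,
) -> SmoothedMUA:
    """Summed population spike counts, binned and Gaussian-smoothed.

    ``unit_ids`` selects the contributing units (e.g. all cortical units);
    the kernel integrates to one so total spike count is preserved.
    """
    ids = list(unit_ids) if unit_ids is not None else spikes.unit_ids()
    if not ids:
        raise ValueError("empty unit set")
    all_times = np.concatenate([spikes[u] for u in ids]) if ids else np.empty(0)
    if t_end is None:
        t_end = float(all_times.max()) + 1.0 if all_times.size else t_start + 1.0
    dt = bin_ms * 1e-3
    n_bins = int(np.ceil((t_end - t_start) / dt))
    edges = t_start + np.arange(n_bins + 1) * dt
    counts = np.histogram(all_times, bins=edges)[0].astype(float)
    kernel = gaussian_kernel(kernel_ms / bin_ms)
    smoothed = np.convolve(counts, kernel, mode="same")
    return SmoothedMUA(values=smoothed, bin_s=dt, t0=t_start,
                       kernel_sd_ms=kernel_ms, n_units=len(ids))


def mask_from_intervals(
    mua: SmoothedMUA, intervals: list[tuple[float, float]]
) -> np.ndarray:
    """Boolean mask over MUA bins covered by the given time intervals."""
    mask = np.zeros(mua.values.size, dtype=bool)
    n = mask.size
    for t0, t1 in intervals:
        i0 = max(0, int(np.floor((t0 - mua.t0) / mua.bin_s)))
        i1 = min(n, int(np.ceil((t1 - mua.t0) / mua.bin_s)))
        mask[i0:i1] = True
    return mask


def detect_up_states(
    mua: SmoothedMUA,
    spontaneous_mask: np.ndarray,
    pre_window_ms: float = PRE_WINDOW_MS,
    pre_fraction: float = PRE_FRACTION,
    up_window_ms: float = UP_WINDOW_MS,
    strict_above: bool = True,
    floor: float | None = None,
) -> tuple[StateEpochs, float]:
    """Detect UP-state onsets in smoothed MUA over spontaneous periods.

    Threshold = geometric mean of the smoothed MUA over all spontaneous
    bins, with bins clipped from below at a positivity floor (default: half
    of a single spike's peak kernel contribution) so the geometric mean is
    well-defined in the presence of silent bins while still reflecting the
    near-zero DOWN-state bins.  Onset criteria:

    1. the MUA crosses above threshold (previous bin <= theta < current);
    2. mean MUA over the preceding 100 ms is below 20% of threshold;
    3. the MUA remains above threshold for the full 200 ms after onset
       (every bin, strict reading; ``strict_above=False`` relaxes this to
       the window mean).

    Each retained UP state is reported as the 200 ms window from its onset.
    Returns (epochs, threshold).
    """
    v = mua.values
    mask = np.asarray(spontaneous_mask, dtype=bool)
    if mask.shape != v.shape:
        raise ValueError("mask must match the MUA length")
    if not mask.any():
        raise ValueError("empty spontaneous mask")
    if not np.any(v[mask] > 0):
        raise ValueError("no activity in spontaneous periods")

    if floor is None:
        floor = 0.5 * mua.kernel_peak()
    clipped = np.maximum(v[mask], floor)
    theta = float(np.exp(np.mean(np.log(clipped))))
    if theta <= floor:
        raise ValueError("no activity above floor in spontaneous periods")

    n_pre = int(round(pre_window_ms * 1e-3 / mua.bin_s))
    n_up = int(round(up_window_ms * 1e-3 / mua.bin_s))
    crossings = np.flatnonzero((v[1:] > theta) & (v[:-1] <= theta)) + 1

    epochs = []
    last_end = -1
    for i in crossings:
        if i < n_pre or i + n_up > v.size:
            continue
        # whole pre-window + UP window must lie in spontaneous periods
        if not mask[i - n_pre:i + n_up].all():
            continue
        if i < last_end:  # no overlapping UP states
            continue
        if v[i - n_pre:i].mean() >= pre_fraction * theta:
            continue
        win = v[i:i + n_up]
        ok = win.min() > theta if strict_above else win.mean() > theta
        if not ok:
            continue
        t_on = mua.t0 + i * mua.bin_s
        epochs.append((t_on, t_on + up_window_ms * 1e-3, "up_state"))
        last_end = i + n_up
    return StateEpochs(epochs), theta


def define_state_epochs(
    events: EventTable,
    spont_window_s: float = SPONT_WINDOW_S,
    desync_len_s: float = DESYNC_LEN_S,
) -> StateEpochs:
    """Synchronized / desynchronized epochs around BF stimulations.

    Per stimulation pair (bf_on, bf_off): synchronized epoch
    [bf_on - 3 s, bf_on) and desynchronized epoch (bf_off, bf_off + 3 s],
    the latter truncated at the next bf_on.  ``desync_len_s`` records the
    assumed duration of the induced desynchronized state (used by trial
    assignment when block labels are absent); epochs themselves use the 3 s
    spontaneous-analysis windows.
    """
    pairs = events.bf_pairs()
    epochs: list[tuple[float, float, str]] = []
    if not pairs:
        return StateEpochs([])
    ons = [p[0] for p in pairs]
    for k, (on, off) in enumerate(pairs):
        sync0 = max(0.0, on - spont_window_s)
        if on > sync0:
            epochs.append((sync0, on, "synchronized"))
        d_end = off + spont_window_s
        if k + 1 < len(ons):
            d_end = min(d_end, ons[k + 1])
        if d_end > off:
            epochs.append((off, d_end, "desynchronized"))
    return StateEpochs(epochs)


def assign_trial_states(
    events: EventTable, kinds: tuple[str, ...] = ("click",)
) -> dict[str, np.ndarray]:
    """Map stimulus events to a cortical state via their block labels.

    Trials in ``stim`` blocks (each trial preceded by BF stimulation) are
    desynchronized; trials in ``no_stim`` blocks are synchronized.
    """
    df = events.df[events.df["kind"].isin(kinds)]
    out = {}
    for state, kind in (("synchronized", "no_stim"), ("desynchronized", "stim")):
        out[state] = df[df["block_kind"] == kind]["time_s"].to_numpy()
    return out
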
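"""Current-source-density analysis and laminar depth alignment.

Recording depth is aligned across sessions by locating the thalamic recipient
layer (presumptive L3/4): the laminar LFP is smoothed across adjacent
channels, the CSD is taken as the negated second spatial difference, and the
channel carrying the largest click-evoked sink (most negative CSD) defines
relative depth 0.  Unit somatic depth is the channel of maximum
trough-to-peak waveform amplitude.

Sign convention: sinks (net inward transmembrane current) are negative.
Conductivity is set to 1 (arbitrary units); only the location of the sink
matters for alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import LaminarLFP, UnitMeta

#: default click-triggered window for sink search, ms after click onset
DEFAULT_SINK_WINDOW_MS = (0.0, 50.0)


class NoSinkError(ValueError):
    """The evoked CSD is flat; no sink can be localized."""


@dataclass
class CSDProfile:
    """CSD matrix (channels x time), units of microvolt / h**2 with h the
    inter-channel spacing; negative values denote sinks."""

    values: np.ndarray
    fs: float
    spacing_um: float
    t0: float = 0.0
    aligned: bool = False

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _pad_dup(x: np.ndarray) -> np.ndarray:
    """Duplicate the uppermost and lowermost channels (Vaknin padding)."""
    return np.vstack([x[:1], x, x[-1:]])


def smooth_depth(lfp: LaminarLFP) -> LaminarLFP:
    """Smooth the LFP across spatially adjacent channels.

    Applies the triangular kernel
    ``phi_s(r) = [phi(r - h) + 2 phi(r) + phi(r + h)] / 4``
    after duplicating the uppermost and lowermost channels, so the output
    keeps the original channel count.  Constants and depth-linear profiles
    pass through unchanged on interior channels.
    """
    if lfp.n_channels < 2:
        raise ValueError("smoothing requires at least 2 channels")
    p = _pad_dup(lfp.samples)
    sm = (p[:-2] + 2.0 * p[1:-1] + p[2:]) / 4.0
    return lfp.copy_with(samples=sm)


def compute_csd(lfp: LaminarLFP) -> CSDProfile:
    """Negated second spatial difference of the (smoothed) laminar LFP.

    ``CSD(r, t) = -[phi(r+h, t) - 2 phi(r, t) + phi(r-h, t)] / h**2``
    with boundary channels handled by the same duplication rule as
    :func:`smooth_depth`.  The caller is expected to compose
    ``compute_csd(smooth_depth(lfp))``.
    """
    if lfp.n_channels < 3:
        raise ValueError("CSD requires at least 3 channels")
    h = lfp.spacing_um
    p = _pad_dup(lfp.samples)
    csd = -(p[2:] - 2.0 * p[1:-1] + p[:-2]) / h**2
    return CSDProfile(values=csd, fs=lfp.fs, spacing_um=h, t0=lfp.t0)


def click_triggered_csd(
    csd: CSDProfile,
    click_times: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_SINK_WINDOW_MS,
    baseline_ms: tuple[float, float] = (-50.0, 0.0),
) -> np.ndarray:
    """Average CSD over click-triggered windows -> (channels x window) matrix.

    Each trial is baseline-corrected by subtracting the per-channel mean CSD
    over the pre-click ``baseline_ms`` window (standard evoked-potential
    practice; it removes ongoing slow-oscillation leakage that would
    otherwise mask the evoked sink).  Set ``baseline_ms=None`` to disable.
    """
    click_times = np.asarray(click_times, dtype=float)
    if click_times.size == 0:
        raise ValueError("no clicks in session")
    i0 = int(round(window_ms[0] * 1e-3 * csd.fs))
    i1 = int(round(window_ms[1] * 1e-3 * csd.fs))
    if i1 <= i0:
        raise ValueError("empty sink-search window")
    n = csd.values.shape[1]
    segs = []
    for t in click_times:
        k = int(round((t - csd.t0) * csd.fs))
        if k + i0 < 0 or k + i1 > n:
            continue
        seg = csd.values[:, k + i0:k + i1]
        if baseline_ms is not None:
            b0 = k + int(round(baseline_ms[0] * 1e-3 * csd.fs))
            b1 = k + int(round(baseline_ms[1] * 1e-3 * csd.fs))
            if b0 >= 0 and b1 > b0:
                seg = seg - csd.values[:, b0:b1].mean(axis=1, keepdims=True)
        segs.append(seg)
    if not segs:
        raise ValueError("no clicks with a complete window inside the recording")
    return np.mean(segs, axis=0)


def find_recipient_channel(
    csd: CSDProfile,
    click_times: np.ndarray,
    window_ms: tuple[float, float] = DEFAULT_SINK_WINDOW_MS,
) -> int:
    """Channel with the largest click-evoked sink (most negative mean CSD).

    Ties break toward the more superficial channel (smaller index).  A flat
    evoked CSD raises :class:`NoSinkError`.
    """
    avg = click_triggered_csd(csd, click_times, window_ms)
    per_channel_min = avg.min(axis=1)
    span = float(avg.max() - avg.min())
    if span == 0.0 or per_channel_min.min() >= 0:
        raise NoSinkError("no sink found: evoked CSD has no negative deflection")
    return int(np.argmin(per_channel_min))


def assign_relative_depths(
    units: list[UnitMeta], recipient_channel: int, spacing_um: float
) -> list[UnitMeta]:
    """Assign ``relative_depth_um`` = (recipient - depth_channel) * spacing.

    Index 0 is superficial, so channels above the recipient layer get
    positive depths (toward the pia).  Units are modified in place and
    returned.
    """
    for u in units:
        if u.depth_channel is None:
            raise ValueError(f"unit {u.unit_id} has no depth channel")
        u.relative_depth_um = float(
            (recipient_channel - u.depth_channel) * spacing_um
        )
    return units


def estimate_unit_depth(mean_waveform: np.ndarray) -> int:
    """Somatic channel estimate: argmax of per-channel trough-to-peak amplitude.

    Amplitude on each channel is (max - min) of the mean waveform; ties break
    toward the superficial channel.  An all-zero waveform has no depth.
    """
    wf = np.asarray(mean_waveform, dtype=float)
    amp = wf.max(axis=1) - wf.min(axis=1)
    if np.all(amp == 0):
        raise ValueError("all-zero waveform: cannot estimate depth")
    return int(np.argmax(amp))
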
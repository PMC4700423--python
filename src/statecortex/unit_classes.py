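"""Cell-type classification from spike-waveform width and laminar depth.

Cortical units split at a trough-to-peak duration of 0.55 ms into
narrow-spiking (NS, putative fast-spiking interneurons) and broad-spiking
(BS, putative pyramidal) cells.  BS cells are subdivided by relative depth
(0 at the thalamic recipient layer, positive toward the pia):

=====  ==================  =====================
class  depth bin (um)       approximate layer
=====  ==================  =====================
BS1     0 to +200           L2/3
BS2    -300 to 0            L3/4
BS3    -700 to -300         L5
BS4    -1100 to -700        L6
=====  ==================  =====================

Shared bin edges are assigned lower-edge-inclusive to the deeper bin, except
the topmost edges (0 and +200) which close BS1, so the bins partition
[-1100, +200] exactly.  Thalamic (MGB) units keep class MGB regardless of
waveform width.  A width of exactly 0.55 ms counts as broad-spiking.
"""

from __future__ import annotations

import numpy as np

#: trough-to-peak split between narrow- and broad-spiking cells, ms
NS_BS_SPLIT_MS = 0.55

#: BS depth bins, superficial edge first: (lo, hi, class); lo-inclusive,
#: hi-exclusive except the topmost bin which includes +200.
BS_DEPTH_BINS = (
    (0.0, 200.0, "BS1"),
    (-300.0, 0.0, "BS2"),
    (-700.0, -300.0, "BS3"),
    (-1100.0, -700.0, "BS4"),
)


def trough_to_peak(mean_waveform_channel: np.ndarray, wave_fs: float) -> float:
    """Trough-to-peak time of a mean spike waveform, in ms.

    Measured on the depth channel's mean waveform as the time from the
    global trough (minimum) to the subsequent maximum.  Monotone or flat
    waveforms have no trough-then-peak and raise ``ValueError``.
    """
    w = np.asarray(mean_waveform_channel, dtype=float)
    if w.ndim != 1:
        raise ValueError("expected a single-channel waveform")
    if w.size < 2 or np.ptp(w) == 0:
        raise ValueError("non-biphasic waveform")
    i_trough = int(np.argmin(w))
    after = w[i_trough + 1:]
    if after.size == 0 or after.max() <= w[i_trough]:
        raise ValueError("non-biphasic waveform")
    i_peak = i_trough + 1 + int(np.argmax(after))
    return (i_peak - i_trough) / wave_fs * 1e3


def classify_unit(
    ttp_ms: float, relative_depth_um: float | None, area: str = "AC"
) -> str:
    """Assign a cell class from waveform width, depth and recording area.

    MGB units are class ``MGB`` regardless of width.  Cortical units with
    ttp < 0.55 ms are ``NS`` at any depth; broader units fall into BS1-BS4
    by depth bin, or ``unclassified`` outside [-1100, +200] um.
    """
    if area == "MGB":
        return "MGB"
    if not np.isfinite(ttp_ms):
        raise ValueError("non-finite trough-to-peak duration")
    if ttp_ms < NS_BS_SPLIT_MS:
        return "NS"
    if relative_depth_um is None or not np.isfinite(relative_depth_um):
        return "unclassified"
    d = relative_depth_um
    if 0.0 <= d <= 200.0:
        return "BS1"
    if -300.0 <= d < 0.0:
        return "BS2"
    if -700.0 <= d < -300.0:
        return "BS3"
    if -1100.0 <= d < -700.0:
        return "BS4"
    return "unclassified"


def classify_units(units, wave_fs: float | None = None) -> None:
    """Fill ``trough_to_peak_ms`` and ``cell_class`` on UnitMeta records.

    Width is measured on each unit's depth channel; units whose depth channel
    is unset fall back to the channel of maximum amplitude.
    """
    from .laminar import estimate_unit_depth

    for u in units:
        ch = u.depth_channel
        if ch is None:
            ch = estimate_unit_depth(u.mean_waveform)
            u.depth_channel = ch
        fs = wave_fs if wave_fs is not None else u.wave_fs
        u.trough_to_peak_ms = trough_to_peak(u.mean_waveform[ch], fs)
        u.cell_class = classify_unit(u.trough_to_peak_ms, u.relative_depth_um, u.area)
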
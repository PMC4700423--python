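"""LFP preprocessing, power spectral densities and band-power state indices.

Raw broadband signals are zero-phase low-pass filtered below 200 Hz and
resampled to 1 kHz before any spectral analysis.  PSDs (microvolt^2/Hz,
0-100 Hz) are estimated per channel with a multitaper estimator (DPSS
tapers, default time-bandwidth NW = 3) or Welch's method; the state
comparisons integrate over bands, so they are robust to the estimator
choice.  Fixed analysis bands: delta 0-4, theta 4-8, alpha 8-12, beta 12-30
and low-gamma 30-50 Hz.  The low-frequency state index (total power at
<= 7 Hz on a deep channel, sliding window) tracks desynchronization and
recovery after basal-forebrain stimulation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .core_io import LaminarLFP
from .response_stats import modulation_index

TARGET_FS = 1000.0
LOWPASS_HZ = 200.0
PSD_FMAX = 100.0
STATE_INDEX_FMAX = 7.0

#: fixed analysis bands (Hz)
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 50.0),
}


def preprocess_lfp(
    raw: LaminarLFP,
    cutoff_hz: float = LOWPASS_HZ,
    target_fs: float = TARGET_FS,
    numtaps: int = 257,
) -> LaminarLFP:
    """Zero-phase low-pass (< 200 Hz, FIR) then resample to 1 kHz.

    Input already at the target rate is filtered but not resampled.  The
    sampling theorem requires ``fs > 2 * cutoff``.
    """
    fs = raw.fs
    if fs < 2 * cutoff_hz:
        raise ValueError(
            f"fs={fs} Hz violates the sampling theorem for a {cutoff_hz} Hz cutoff"
        )
    taps = signal.firwin(numtaps, cutoff_hz, fs=fs)
    filtered = signal.filtfilt(taps, [1.0], raw.samples, axis=1)
    if fs == target_fs:
        return raw.copy_with(samples=filtered)
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    n_target = int(round(raw.n_samples * target_fs / fs))
    out = out[:, :n_target]
    return raw.copy_with(samples=out, fs=target_fs)


def compute_psd(
    samples: np.ndarray,
    fs: float,
    method: str = "multitaper",
    nw: float = 3.0,
    nperseg: int | None = None,
    fmax: float = PSD_FMAX,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel PSD of an LFP segment over 0-``fmax`` Hz.

    Parameters
    ----------
    samples : (n_channels, n_samples) or (n_samples,) array, microvolts.
    method : "multitaper" (DPSS tapers, time-bandwidth ``nw``) or "welch".
    nperseg : Welch segment length (default min(n, fs)); ignored for
        multitaper, which tapers the whole segment.

    Returns
    -------
    freqs : (n_freqs,) Hz, restricted to [0, fmax].
    psd : (n_channels, n_freqs) in microvolt^2/Hz.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    n = x.shape[1]
    if n < fs:
        raise ValueError("segment shorter than 1 s")
    if method == "welch":
        nps = int(nperseg or min(n, int(fs)))
        freqs, psd = signal.welch(x, fs=fs, nperseg=nps, axis=1)
    elif method == "multitaper":
        k = max(1, int(2 * nw) - 1)
        tapers, ratios = signal.windows.dpss(n, nw, Kmax=k, return_ratios=True)
        # average taper periodograms weighted by concentration ratios
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        psd = np.zeros((x.shape[0], freqs.size))
        for taper, lam in zip(tapers, ratios):
            spec = np.fft.rfft(x * taper[None, :], axis=1)
            psd += lam * (np.abs(spec) ** 2)
        psd /= ratios.sum()
        psd *= 2.0 / fs  # one-sided density; taper has unit energy
        psd[:, 0] /= 2.0
        if n % 2 == 0:
            psd[:, -1] /= 2.0
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    keep = freqs <= fmax
    return freqs[keep], psd[:, keep]


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> np.ndarray:
    """Integrate the PSD over a frequency band (trapezoid rule) per channel.

    Adjacent bands share their edge frequency, so band powers add exactly to
    the power of the union.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty band")
    psd = np.atleast_2d(psd)
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        raise ValueError("band narrower than the frequency resolution")
    return np.trapezoid(psd[:, mask], freqs[mask], axis=1)


def band_power_table(
    segments_by_state: dict[str, list[np.ndarray]],
    fs: float,
    method: str = "multitaper",
    nw: float = 3.0,
    bands: dict[str, tuple[float, float]] = BANDS,
) -> pd.DataFrame:
    """Mean band power per (channel, band, state) over epoch segments.

    ``segments_by_state`` maps a state label to a list of
    (n_channels, n_samples) LFP segments (e.g. the 3 s windows before /
    after each BF stimulation).  PSDs are averaged across segments before
    band integration.
    """
    rows = []
    for state, segments in segments_by_state.items():
        if not segments:
            continue
        psds = []
        freqs = None
        n_min = min(s.shape[1] for s in segments)
        for seg in segments:
            f, p = compute_psd(seg[:, :n_min], fs, method=method, nw=nw)
            freqs, psds = f, psds + [p]
        mean_psd = np.mean(psds, axis=0)
        for band_name, band in bands.items():
            bp = band_power(freqs, mean_psd, band)
            for ch, power in enumerate(bp):
                rows.append({"channel": ch, "band": band_name,
                             "state": state, "power": float(power)})
    return pd.DataFrame(rows)


def band_power_state_mi(table: pd.DataFrame) -> pd.DataFrame:
    """Modulation index (desync - sync)/(desync + sync) per (channel, band)."""
    pivot = table.pivot_table(
        index=["channel", "band"], columns="state", values="power"
    )
    for state in ("synchronized", "desynchronized"):
        if state not in pivot.columns:
            raise ValueError(f"band-power table lacks state {state!r}")
    rows = []
    for (ch, band), row in pivot.iterrows():
        s, d = row["synchronized"], row["desynchronized"]
        rows.append({
            "channel": ch, "band": band,
            "mi": modulation_index(s, d) if s + d > 0 else float("nan"),
        })
    return pd.DataFrame(rows)


def state_index(
    lfp: LaminarLFP,
    channel: int,
    window_s: float = 2.0,
    step_s: float = 0.5,
    fmax: float = STATE_INDEX_FMAX,
    method: str = "welch",
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window total power at <= 7 Hz on one (deep) channel.

    Returns (window-center times in session seconds, power values).  Low
    values flag the desynchronized state; the index recovers to its
    synchronized-state level within ~10 s of BF stimulation offset.
    """
    if window_s < 1.0:
        raise ValueError("window must be at least 1 s")
    n_win = int(round(window_s * lfp.fs))
    n_step = int(round(step_s * lfp.fs))
    x = lfp.samples[channel]
    if n_win > x.size:
        raise ValueError("window longer than signal")
    starts = np.arange(0, x.size - n_win + 1, n_step)
    centers = lfp.t0 + (starts + n_win / 2) / lfp.fs
    powers = np.empty(starts.size)
    for i, s0 in enumerate(starts):
        seg = x[s0:s0 + n_win]
        if np.all(seg == 0):
            powers[i] = 0.0
            continue
        freqs, psd = compute_psd(seg, lfp.fs, method=method, fmax=fmax)
        powers[i] = float(np.trapezoid(psd[0], freqs))
    return centers, powers
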
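"""Synthetic laminar sessions with known ground truth.

Generates sessions that reproduce the statistical structure of laminar
auditory thalamocortical recordings under basal-forebrain (BF) induced state
changes, so that every analysis stage has a recoverable answer:

* two cortical states — a synchronized state with slow (0.5-2 Hz)
  oscillations weighted toward deep channels and UP/DOWN firing
  alternation, and a BF-induced desynchronized state (default 10 s after
  each stimulation offset) with attenuated low-frequency power, a
  superficial 30-50 Hz narrowband component and tonic firing;
* cell-class-specific spontaneous rates (BS1/BS4 firing drops in the
  desynchronized state);
* click-evoked responses with an onset peak, a suppression trough and a
  rebound whose timing is earlier in the desynchronized state in cortex
  (thalamic units respond with onset + sustained decay, state-invariant
  timing); narrow-spiking onset responses grow while broad-spiking ones
  shrink in the desynchronized state, and trial-to-trial response gain is
  more variable in the synchronized state;
* von Mises phase-locked click-train responses whose concentration kappa
  rises in the desynchronized state in cortex but not in thalamus;
* a click-evoked LFP sink on the thalamic recipient channel, and biphasic
  unit waveforms whose trough-to-peak width and depth channel encode the
  true cell class.

Determinism: all randomness derives from one integer seed through
``numpy.random.SeedSequence(seed, spawn_key=(stream, index))`` with a fixed
stream id per component and one stream per unit, so adding a unit never
perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core_io import (EventTable, LaminarLFP, Session, SpikeTrainSet,
                      UnitMeta, ValidationError)
from .unit_classes import classify_unit

# RNG stream ids
_STREAM_SESSION = 0
_STREAM_LFP = 1
_STREAM_UNIT_SPIKES = 2
_STREAM_UNIT_WAVE = 3


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All generator parameters; defaults encode the emulated study design."""

    # geometry / sampling
    n_channels: int = 32
    fs: float = 1000.0
    spacing_um: float = 50.0
    recipient_channel: int = 8
    wave_fs: float = 20000.0
    n_wave_samples: int = 64

    # unit counts per class
    n_ns: int = 12
    n_bs1: int = 12
    n_bs2: int = 12
    n_bs3: int = 12
    n_bs4: int = 12
    n_mgb: int = 20

    # session layout
    n_spont_stims: int = 6
    spont_period_s: float = 30.0
    n_click_trials: int = 25
    click_trial_s: float = 3.0
    stim_trial_s: float = 3.5
    n_trains_per_freq: int = 6
    train_trial_s: float = 2.5
    block_gap_s: float = 10.0
    recovery_s: float = 30.0
    bf_dur_s: float = 1.0
    desync_len_s: float = 10.0  # desynchronization outlasts bf_off by this

    # UP/DOWN alternation (synchronized state)
    up_median_s: float = 0.4
    down_median_s: float = 0.3
    updown_sigma: float = 0.5
    down_rate_hz: float = 0.1
    up_duty: float = 0.6  # nominal UP fraction; r_up = rate_sync / up_duty

    # spontaneous tonic rates per class (Hz) and desynchronized-state factor
    rate_sync_hz: dict = field(default_factory=lambda: {
        "NS": 8.0, "BS1": 2.0, "BS2": 5.0, "BS3": 6.0, "BS4": 2.0, "MGB": 8.0})
    desync_rate_factor: dict = field(default_factory=lambda: {
        "NS": 1.0, "BS1": 0.5, "BS2": 1.0, "BS3": 1.0, "BS4": 0.5, "MGB": 1.0})
    rate_jitter_sigma: float = 0.2  # per-unit log-normal rate jitter

    # click-evoked response template
    onset_time_ms: float = 15.0
    onset_sd_ms: float = 6.0
    onset_spikes_sync: dict = field(default_factory=lambda: {
        "NS": 1.5, "BS1": 1.5, "BS2": 1.5, "BS3": 1.5, "BS4": 1.5, "MGB": 2.0})
    onset_desync_factor: dict = field(default_factory=lambda: {
        "NS": 1.5, "BS1": 0.65, "BS2": 0.65, "BS3": 0.65, "BS4": 0.65,
        "MGB": 0.9})
    rebound_time_sync_ms: float = 150.0
    rebound_time_desync_ms: float = 120.0
    rebound_sd_ms: float = 20.0
    rebound_spikes: float = 0.8
    suppression_start_ms: float = 30.0
    suppression_margin_ms: float = 30.0
    mgb_sustained_spikes: float = 1.0
    mgb_sustained_tau_ms: float = 40.0
    trial_gain_sigma_sync: float = 0.6
    trial_gain_sigma_desync: float = 0.15

    # click-train phase locking
    train_freqs: tuple = (4, 8, 16, 32, 64)
    train_len_s: float = 1.0
    locked_rate_hz: dict = field(default_factory=lambda: {"AC": 20.0, "MGB": 25.0})
    kappa_sync: dict = field(default_factory=lambda: {"AC": 0.8, "MGB": 1.5})
    kappa_desync: dict = field(default_factory=lambda: {"AC": 2.0, "MGB": 1.5})

    # LFP composition (microvolts)
    noise_amp_uv: float = 20.0
    slow_amp_uv: float = 150.0
    slow_desync_factor: float = 0.25
    slow_band_hz: tuple = (0.5, 2.0)
    gamma_amp_uv: float = 30.0
    gamma_sync_factor: float = 0.0
    gamma_band_hz: tuple = (30.0, 50.0)
    gamma_depth_decay_ch: float = 6.0
    crossfade_s: float = 0.5
    evoked_amp_uv: float = 100.0
    evoked_time_ms: float = 12.0
    evoked_sd_ms: float = 5.0
    evoked_spatial_sd_ch: float = 1.5

    # waveforms
    wave_trough_uv: float = 60.0
    wave_peak_frac: float = 0.45
    wave_spatial_sd_ch: float = 1.5
    wave_noise_uv: float = 1.0
    ttp_ns_range_ms: tuple = (0.20, 0.45)
    ttp_bs_range_ms: tuple = (0.60, 1.00)
    ttp_mgb_range_ms: tuple = (0.20, 0.50)

    # unit isolation quality
    quality_range: tuple = (18.0, 40.0)

    # housekeeping
    level_db: float = 70.0
    session_pad_s: float = 15.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.n_channels < 3:
            raise ValidationError("need at least 3 channels")
        for cls_name, r in self.rate_sync_hz.items():
            if r < 0:
                raise ValidationError(f"negative rate for {cls_name}")
        if self.n_spont_stims < 1:
            raise ValidationError("zero-length session: no spontaneous block")


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream, index))
    )


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class UnitGroundTruth:
    unit_id: int
    area: str
    cell_class: str
    depth_channel: int
    relative_depth_um: float
    ttp_ms: float
    quality: float
    rate_sync: float
    rate_desync: float
    r_up: float
    r_down: float
    onset_spikes: dict          # state -> expected onset spikes per trial
    rebound_time_ms: dict       # state -> rebound center (AC), NaN for MGB
    kappa: dict                 # state -> {train_hz: kappa}
    locked_rate: float


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    state_schedule: list        # (t0, t1, label) sync/desync covering session
    up_intervals: list          # (t0, t1) true UP states (synchronized only)
    units: list                 # UnitGroundTruth per unit
    recipient_channel: int
    seed: int
    config: SimConfig
    session_len_s: float = 0.0

    def unit(self, unit_id: int) -> UnitGroundTruth:
        return next(u for u in self.units if u.unit_id == unit_id)


# ---------------------------------------------------------------------------
# session layout: events and state schedule
# ---------------------------------------------------------------------------

def build_events(cfg: SimConfig, rng: np.random.Generator) -> EventTable:
    """Construct the block-design event table.

    Blocks, in order: a sound-free spontaneous block with repeated BF
    stimulations; single-click blocks without and with per-trial BF
    stimulation; click-train blocks without and with per-trial BF
    stimulation.  Train frequencies are shuffled within each repetition.
    """
    rows = []

    def add(t, kind, level=np.nan, hz=np.nan, block="", bkind=""):
        rows.append({"time_s": t, "kind": kind, "level_db": level,
                     "train_hz": hz, "block_id": block, "block_kind": bkind})

    t = 10.0
    for _ in range(cfg.n_spont_stims):
        add(t, "bf_on", block="spont", bkind="stim")
        add(t + cfg.bf_dur_s, "bf_off", block="spont", bkind="stim")
        t += cfg.spont_period_s
    t += cfg.block_gap_s

    for k in range(cfg.n_click_trials):
        add(t + 0.5, "click", level=cfg.level_db, block="click_ns",
            bkind="no_stim")
        t += cfg.click_trial_s
    t += cfg.block_gap_s

    for k in range(cfg.n_click_trials):
        add(t, "bf_on", block="click_st", bkind="stim")
        add(t + cfg.bf_dur_s, "bf_off", block="click_st", bkind="stim")
        add(t + cfg.bf_dur_s + 0.5, "click", level=cfg.level_db,
            block="click_st", bkind="stim")
        t += cfg.stim_trial_s
    t += cfg.recovery_s

    for rep in range(cfg.n_trains_per_freq):
        freqs = list(cfg.train_freqs)
        rng.shuffle(freqs)
        for hz in freqs:
            add(t + 0.5, "train_onset", level=cfg.level_db, hz=hz,
                block="train_ns", bkind="no_stim")
            add(t + 0.5 + cfg.train_len_s, "train_offset", block="train_ns",
                bkind="no_stim")
            t += cfg.train_trial_s
    t += cfg.block_gap_s

    for rep in range(cfg.n_trains_per_freq):
        freqs = list(cfg.train_freqs)
        rng.shuffle(freqs)
        for hz in freqs:
            add(t, "bf_on", block="train_st", bkind="stim")
            add(t + cfg.bf_dur_s, "bf_off", block="train_st", bkind="stim")
            add(t + cfg.bf_dur_s + 0.5, "train_onset", level=cfg.level_db,
                hz=hz, block="train_st", bkind="stim")
            add(t + cfg.bf_dur_s + 0.5 + cfg.train_len_s, "train_offset",
                block="train_st", bkind="stim")
            t += cfg.bf_dur_s + cfg.train_trial_s
    t += cfg.session_pad_s

    df = pd.DataFrame(rows).sort_values("time_s", kind="stable")
    return EventTable(df.reset_index(drop=True)), t


def build_state_schedule(
    events: EventTable, session_len_s: float, desync_len_s: float
) -> list[tuple[float, float, str]]:
    """True sync/desync intervals: desynchronization starts at bf_on and
    lasts ``desync_len_s`` beyond bf_off, truncated at the next bf_on."""
    pairs = events.bf_pairs()
    desync: list[list[float]] = []
    for k, (on, off) in enumerate(pairs):
        end = off + desync_len_s
        if k + 1 < len(pairs):
            end = min(end, pairs[k + 1][0])
        end = min(end, session_len_s)
        if desync and on <= desync[-1][1]:
            desync[-1][1] = max(desync[-1][1], end)
        else:
            desync.append([on, end])
    schedule: list[tuple[float, float, str]] = []
    cursor = 0.0
    for d0, d1 in desync:
        if d0 > cursor:
            schedule.append((cursor, d0, "synchronized"))
        schedule.append((d0, d1, "desynchronized"))
        cursor = d1
    if cursor < session_len_s:
        schedule.append((cursor, session_len_s, "synchronized"))
    return schedule


def draw_up_down_intervals(
    sync_intervals: list[tuple[float, float]],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Log-normal UP/DOWN alternation filling the synchronized intervals."""
    mu_up = np.log(cfg.up_median_s)
    mu_down = np.log(cfg.down_median_s)
    ups = []
    for t0, t1 in sync_intervals:
        t = t0
        while t < t1:
            t += float(rng.lognormal(mu_down, cfg.updown_sigma))  # DOWN first
            if t >= t1:
                break
            dur = float(rng.lognormal(mu_up, cfg.updown_sigma))
            ups.append((t, min(t + dur, t1)))
            t += dur
    return ups


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

def draw_units(cfg: SimConfig, seed: int) -> list[UnitGroundTruth]:
    rng = _rng(seed, _STREAM_SESSION, 1)
    specs: list[tuple[str, str]] = (
        [("AC", "NS")] * cfg.n_ns + [("AC", "BS1")] * cfg.n_bs1
        + [("AC", "BS2")] * cfg.n_bs2 + [("AC", "BS3")] * cfg.n_bs3
        + [("AC", "BS4")] * cfg.n_bs4 + [("MGB", "MGB")] * cfg.n_mgb
    )
    depth_bins = {"BS1": (0.0, 200.0), "BS2": (-300.0, 0.0),
                  "BS3": (-700.0, -300.0), "BS4": (-1100.0, -700.0)}
    units = []
    for uid, (area, cls) in enumerate(specs):
        if area == "MGB":
            ttp = float(rng.uniform(*cfg.ttp_mgb_range_ms))
            ch = int(rng.integers(4, cfg.n_channels - 4))
            depth = np.nan
        else:
            if cls == "NS":
                ttp = float(rng.uniform(*cfg.ttp_ns_range_ms))
                # NS at any depth spanned by the probe
                lo_ch = cfg.recipient_channel - 4
                hi_ch = min(cfg.n_channels - 1, cfg.recipient_channel + 22)
                ch = int(rng.integers(max(0, lo_ch), hi_ch + 1))
            else:
                ttp = float(rng.uniform(*cfg.ttp_bs_range_ms))
                lo_d, hi_d = depth_bins[cls]
                # channel offsets whose depth lands inside the class bin,
                # matching the half-open bin convention
                h = cfg.spacing_um
                cands = [
                    c for c in range(cfg.n_channels)
                    if classify_unit(ttp, (cfg.recipient_channel - c) * h, "AC") == cls
                ]
                ch = int(rng.choice(cands))
            depth = (cfg.recipient_channel - ch) * cfg.spacing_um

        base = cfg.rate_sync_hz[cls]
        jit = float(rng.lognormal(0.0, cfg.rate_jitter_sigma))
        rate_sync = base * jit
        rate_desync = rate_sync * cfg.desync_rate_factor[cls]
        r_up = rate_sync / cfg.up_duty if area == "AC" else rate_sync
        r_down = cfg.down_rate_hz if area == "AC" else rate_sync

        on_sync = cfg.onset_spikes_sync[cls]
        on_desync = on_sync * cfg.onset_desync_factor[cls]
        kappa_key = "MGB" if area == "MGB" else "AC"
        kap_s = cfg.kappa_sync[kappa_key] * float(rng.uniform(0.9, 1.1))
        kap_d = cfg.kappa_desync[kappa_key] * float(rng.uniform(0.9, 1.1))
        if area == "MGB":
            kap_d = kap_s  # thalamic locking is state-invariant
        units.append(UnitGroundTruth(
            unit_id=uid, area=area, cell_class=cls, depth_channel=ch,
            relative_depth_um=float(depth) if np.isfinite(depth) else float("nan"),
            ttp_ms=ttp, quality=float(rng.uniform(*cfg.quality_range)),
            rate_sync=rate_sync, rate_desync=rate_desync,
            r_up=r_up, r_down=r_down,
            onset_spikes={"synchronized": on_sync, "desynchronized": on_desync},
            rebound_time_ms={
                "synchronized": cfg.rebound_time_sync_ms if area == "AC" else float("nan"),
                "desynchronized": cfg.rebound_time_desync_ms if area == "AC" else float("nan"),
            },
            kappa={
                "synchronized": {hz: kap_s for hz in cfg.train_freqs},
                "desynchronized": {hz: kap_d for hz in cfg.train_freqs},
            },
            locked_rate=cfg.locked_rate_hz[kappa_key],
        ))
    return units


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Narrowband Gaussian noise, unit variance."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _state_envelope(schedule, n: int, fs: float, crossfade_s: float) -> np.ndarray:
    """Smooth 0/1 envelope of the desynchronized state (cross-faded)."""
    env = np.zeros(n)
    for t0, t1, label in schedule:
        if label == "desynchronized":
            i0, i1 = int(t0 * fs), min(n, int(t1 * fs))
            env[i0:i1] = 1.0
    m = int(round(crossfade_s * fs))
    if m > 1:
        win = np.hanning(2 * m + 1)
        env = np.convolve(env, win / win.sum(), mode="same")
    return env


def simulate_state_lfp(
    schedule: list[tuple[float, float, str]],
    n_channels: int,
    fs: float,
    seed: int,
    cfg: SimConfig | None = None,
) -> LaminarLFP:
    """Laminar LFP realizing the state schedule.

    Synchronized intervals carry a slow (0.5-2 Hz) oscillation whose
    amplitude grows with depth plus 1/f noise on every channel;
    desynchronized intervals attenuate the slow component and add a 30-50 Hz
    narrowband signal strongest superficially, decaying with depth.  States
    cross-fade smoothly at interval boundaries.
    """
    if not schedule:
        raise ValueError("empty schedule")
    cfg = cfg or SimConfig()
    rng = _rng(seed, _STREAM_LFP)
    t_end = max(t1 for _, t1, _ in schedule)
    n = int(round(t_end * fs))

    env_d = _state_envelope(schedule, n, fs, cfg.crossfade_s)
    env_s = 1.0 - env_d

    slow_env = env_s + cfg.slow_desync_factor * env_d
    gamma_env = env_d + cfg.gamma_sync_factor * env_s

    depth_frac = np.arange(n_channels) / max(1, n_channels - 1)
    slow_gain = cfg.slow_amp_uv * (0.3 + 0.7 * depth_frac)  # deep channels strong
    gamma_gain = cfg.gamma_amp_uv * np.exp(
        -np.arange(n_channels) / cfg.gamma_depth_decay_ch)  # superficial strong

    # narrowband components drawn independently per channel: cross-channel
    # coherence of spontaneous LFP is not modelled (no analysis consumes it)
    samples = np.empty((n_channels, n))
    for ch in range(n_channels):
        samples[ch] = (
            cfg.noise_amp_uv * _pink_noise(n, rng)
            + slow_gain[ch] * _band_noise(n, fs, cfg.slow_band_hz, rng) * slow_env
            + gamma_gain[ch] * _band_noise(n, fs, cfg.gamma_band_hz, rng) * gamma_env
        )
    return LaminarLFP(samples=samples, fs=fs, spacing_um=cfg.spacing_um)


def add_click_evoked_lfp(
    lfp: LaminarLFP, click_times: np.ndarray, cfg: SimConfig
) -> None:
    """Add a click-evoked potential trough on the recipient channel (in place).

    The trough is Gaussian in time (peak ~12 ms post-click) and Gaussian
    across channels around the recipient channel; the resulting CSD sink
    localizes the thalamic recipient layer.
    """
    fs = lfp.fs
    t_rel = np.arange(int(0.06 * fs)) / fs
    temporal = -cfg.evoked_amp_uv * np.exp(
        -0.5 * ((t_rel - cfg.evoked_time_ms * 1e-3) / (cfg.evoked_sd_ms * 1e-3)) ** 2)
    spatial = np.exp(
        -0.5 * ((np.arange(lfp.n_channels) - cfg.recipient_channel)
                / cfg.evoked_spatial_sd_ch) ** 2)
    template = spatial[:, None] * temporal[None, :]
    for t in np.asarray(click_times, dtype=float):
        k = int(round((t - lfp.t0) * fs))
        k1 = min(lfp.n_samples, k + template.shape[1])
        if k < 0 or k1 <= k:
            continue
        lfp.samples[:, k:k1] += template[:, :k1 - k]


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def _interval_mask(n: int, dt: float, intervals) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for t0, t1 in intervals:
        i0 = max(0, int(np.floor(t0 / dt)))
        i1 = min(n, int(np.ceil(t1 / dt)))
        mask[i0:i1] = True
    return mask


def _click_template_rate(
    t_ms: np.ndarray, gt: UnitGroundTruth, state: str, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(evoked rate in Hz on the template grid, baseline suppression mask)."""
    gauss = lambda mu, sd: np.exp(-0.5 * ((t_ms - mu) / sd) ** 2) / (
        sd * 1e-3 * np.sqrt(2 * np.pi))
    rate = gt.onset_spikes[state] * gauss(cfg.onset_time_ms, cfg.onset_sd_ms)
    keep = np.ones_like(t_ms)
    if gt.area == "AC":
        reb = gt.rebound_time_ms[state]
        rate = rate + cfg.rebound_spikes * gauss(reb, cfg.rebound_sd_ms)
        sup0 = cfg.suppression_start_ms
        sup1 = reb - cfg.suppression_margin_ms
        keep[(t_ms >= sup0) & (t_ms < sup1)] = 0.0
    else:
        tau = cfg.mgb_sustained_tau_ms
        sus = np.where(t_ms > 5.0, np.exp(-np.maximum(t_ms - 5.0, 0) / tau), 0.0)
        sus_rate = cfg.mgb_sustained_spikes * sus / (tau * 1e-3)
        rate = rate + sus_rate
    return rate, keep


def simulate_spikes(
    gt: UnitGroundTruth,
    schedule: "GroundTruth",
    events: EventTable,
    seed: int,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike train of one unit over the session.

    Synchronized intervals alternate between UP (rate ``r_up``) and DOWN
    (rate ``r_down``) states shared across cortical units; desynchronized
    intervals are tonic at ``rate_desync``.  Around each single click the
    rate follows the state-specific evoked template (with per-trial
    log-normal gain).  During click trains, spikes are generated per click
    with Poisson counts and von Mises phases of concentration kappa
    (phase 0 = click onset).
    """
    cfg = schedule.config
    rng = _rng(schedule.seed, _STREAM_UNIT_SPIKES, gt.unit_id)
    dt = 1e-3
    n = int(round(schedule.session_len_s / dt))
    rate = np.empty(n)

    desync_mask = _interval_mask(
        n, dt, [(a, b) for a, b, lab in schedule.state_schedule
                if lab == "desynchronized"])
    if gt.area == "AC":
        up_mask = _interval_mask(n, dt, schedule.up_intervals)
        rate[:] = gt.r_down
        rate[up_mask] = gt.r_up
        rate[desync_mask] = gt.rate_desync
    else:
        rate[:] = gt.rate_sync
        rate[desync_mask] = gt.rate_desync

    # single-click evoked windows replace/modulate the baseline
    t_ms = np.arange(0.0, 300.0, 1.0) + 0.5
    templates = {
        s: _click_template_rate(t_ms, gt, s, cfg)
        for s in ("synchronized", "desynchronized")
    }
    gain_sigma = {"synchronized": cfg.trial_gain_sigma_sync,
                  "desynchronized": cfg.trial_gain_sigma_desync}
    clicks = events.of_kind("click")
    for row in clicks.itertuples(index=False):
        state = ("desynchronized" if row.block_kind == "stim"
                 else "synchronized")
        ev_rate, keep = templates[state]
        sig = gain_sigma[state]
        gain = float(rng.lognormal(-0.5 * sig * sig, sig))
        k = int(round(row.time_s / dt))
        k1 = min(n, k + ev_rate.size)
        if k1 <= k:
            continue
        m = k1 - k
        rate[k:k1] = rate[k:k1] * keep[:m] + gain * ev_rate[:m]

    counts = rng.poisson(rate * dt)
    idx = np.repeat(np.arange(n), counts)
    base_times = (idx + rng.random(idx.size)) * dt

    # click-train locked spikes
    locked = []
    for row in events.of_kind("train_onset").itertuples(index=False):
        state = ("desynchronized" if row.block_kind == "stim"
                 else "synchronized")
        hz = int(row.train_hz)
        kappa = gt.kappa[state][hz]
        T = 1.0 / hz
        n_per_click = gt.locked_rate / hz
        n_clicks = int(round(cfg.train_len_s * hz))
        for ck in range(n_clicks):
            m = rng.poisson(n_per_click)
            if m == 0:
                continue
            ph = np.mod(rng.vonmises(0.0, kappa, size=m), 2 * np.pi)
            locked.append(row.time_s + ck * T + ph / (2 * np.pi) * T)
    if locked:
        all_times = np.concatenate([base_times] + locked)
    else:
        all_times = base_times
    all_times = np.unique(all_times)
    return all_times[all_times >= 0]


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def make_waveform(
    ttp_ms: float,
    depth_channel: int,
    n_channels: int,
    wave_fs: float,
    n_wave_samples: int,
    trough_uv: float = 60.0,
    peak_frac: float = 0.45,
    spatial_sd_ch: float = 1.5,
    noise_uv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Biphasic multichannel waveform template.

    Negative Gaussian trough followed by a positive Gaussian peak exactly
    ``ttp_ms`` later (rounded to the waveform sample grid), with Gaussian
    amplitude decay across channels around ``depth_channel``.
    """
    if not 0 <= depth_channel < n_channels:
        raise ValueError("depth channel out of range")
    i_trough = 15
    i_peak = i_trough + int(round(ttp_ms * 1e-3 * wave_fs))
    if i_peak >= n_wave_samples - 2:
        raise ValueError("waveform window too short for requested width")
    i = np.arange(n_wave_samples, dtype=float)
    shape = (-np.exp(-0.5 * ((i - i_trough) / 3.0) ** 2)
             + peak_frac * np.exp(-0.5 * ((i - i_peak) / 4.0) ** 2))
    spatial = np.exp(-0.5 * ((np.arange(n_channels) - depth_channel)
                             / spatial_sd_ch) ** 2)
    wf = trough_uv * spatial[:, None] * shape[None, :]
    if noise_uv > 0 and rng is not None:
        wf = wf + rng.normal(0.0, noise_uv, wf.shape)
    return wf


def simulate_waveforms(
    units: list[UnitGroundTruth], cfg: SimConfig, seed: int
) -> dict[int, np.ndarray]:
    """Mean waveforms for every unit (noise SD ``cfg.wave_noise_uv``)."""
    out = {}
    for gt in units:
        rng = _rng(seed, _STREAM_UNIT_WAVE, gt.unit_id)
        out[gt.unit_id] = make_waveform(
            gt.ttp_ms, gt.depth_channel, cfg.n_channels, cfg.wave_fs,
            cfg.n_wave_samples, trough_uv=cfg.wave_trough_uv,
            peak_frac=cfg.wave_peak_frac, spatial_sd_ch=cfg.wave_spatial_sd_ch,
            noise_uv=cfg.wave_noise_uv, rng=rng,
        )
    return out


# ---------------------------------------------------------------------------
# top-level
# ---------------------------------------------------------------------------

def simulate_session(
    cfg: SimConfig | None = None, seed: int = 0
) -> tuple[Session, GroundTruth]:
    """Generate a full synthetic session plus its ground truth.

    Deterministic given (config, seed).  The returned session satisfies all
    session invariants; the ground truth records the state schedule, true
    UP intervals, per-unit classes, depths, rates, evoked templates and
    phase-locking concentrations.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = _rng(seed, _STREAM_SESSION, 0)

    events, session_len = build_events(cfg, rng)
    schedule = build_state_schedule(events, session_len, cfg.desync_len_s)
    sync_ivals = [(a, b) for a, b, lab in schedule if lab == "synchronized"]
    up_intervals = draw_up_down_intervals(sync_ivals, cfg, rng)

    units_gt = draw_units(cfg, seed)
    gt = GroundTruth(
        state_schedule=schedule, up_intervals=up_intervals, units=units_gt,
        recipient_channel=cfg.recipient_channel, seed=seed, config=cfg,
        session_len_s=session_len,
    )

    trains = {u.unit_id: simulate_spikes(u, gt, events, seed)
              for u in units_gt}
    spikes = SpikeTrainSet(trains)

    lfp = simulate_state_lfp(schedule, cfg.n_channels, cfg.fs, seed, cfg)
    add_click_evoked_lfp(lfp, events.times_of("click"), cfg)

    waveforms = simulate_waveforms(units_gt, cfg, seed)
    units_meta = [
        UnitMeta(
            unit_id=u.unit_id, mean_waveform=waveforms[u.unit_id],
            wave_fs=cfg.wave_fs, quality=u.quality, area=u.area,
        )
        for u in units_gt
    ]

    session = Session(lfp=lfp, spikes=spikes, units=units_meta, events=events)
    return session, gt
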
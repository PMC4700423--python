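"""End-to-end analysis pipeline.

Orchestrates simulate -> preprocess -> CSD/depth alignment -> cell
classification -> state epochs / UP-state detection -> spectral state
indices -> evoked statistics -> click-train phase locking, and writes a
``report.json`` summarizing the state-modulation results: per-class
spontaneous-rate modulation indices, band-power modulation by depth, onset
mean/variance/Fano modulation by class and area, mean-spike-time shifts,
pairwise spike-count correlations per state, and vector-strength modulation
with per-class fractions of significantly locked units.

Every output is stamped with the resolved configuration hash and seed; two
runs with the same config and seed produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import circular, laminar, response_stats, spectral, states, unit_classes
from .core_io import (DEFAULT_MIN_QUALITY, Session, StateEpochs, filter_units,
                      read_session, write_session)
from .synthetic import GroundTruth, SimConfig, simulate_session

log = logging.getLogger("statecortex")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Unknown keys are rejected on load; all defaults are materialized into
    the emitted resolved-config file.
    """

    seed: int = 0
    session_dir: str | None = None      # read an existing session ...
    simulate: bool = True               # ... or generate one
    sim: SimConfig = field(default_factory=SimConfig)

    min_quality: float = DEFAULT_MIN_QUALITY
    psd_method: str = "multitaper"      # or "welch"
    psd_nw: float = 3.0
    sink_window_ms: tuple = laminar.DEFAULT_SINK_WINDOW_MS
    spont_window_s: float = 3.0
    desync_len_s: float = 10.0
    onset_window_ms: tuple = (0.0, 100.0)
    late_window_ms: tuple = (80.0, 200.0)
    state_index_channel: int | None = None  # default: recipient + 8 (deep)
    deep_depth_um: float = -300.0       # channels at or below -> "deep"
    mua_bin_ms: float = 1.0
    mua_kernel_ms: float = 10.0
    strict_up_criterion: bool = True
    exclusion_ms: float = 50.0
    rayleigh_alpha: float = 0.01
    stages: tuple = ("csd", "classify", "states", "spectra", "evoked", "phase")
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig.from_dict(d["sim"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage {stage!r} failed: {msg}")
        self.stage = stage


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def spontaneous_bf_pairs(session: Session) -> list[tuple[float, float]]:
    """BF stimulation pairs delivered in sound-free blocks.

    Spontaneous-state analyses use only stimulations whose block contains no
    click or train events, mirroring the silent recording period used for
    spontaneous activity.
    """
    df = session.events.df
    sound_blocks = set(df[df["kind"].isin(["click", "train_onset"])]["block_id"])
    spont = df[~df["block_id"].isin(sound_blocks)]
    ons = spont[spont["kind"] == "bf_on"]["time_s"].to_numpy()
    offs = spont[spont["kind"] == "bf_off"]["time_s"].to_numpy()
    return list(zip(ons, offs))


def spontaneous_state_epochs(
    session: Session, spont_window_s: float, desync_len_s: float
) -> StateEpochs:
    """3 s synchronized/desynchronized windows around sound-free BF stims."""
    pairs = spontaneous_bf_pairs(session)
    epochs = []
    for on, off in pairs:
        if on - spont_window_s >= 0:
            epochs.append((on - spont_window_s, on, "synchronized"))
        epochs.append((off, off + spont_window_s, "desynchronized"))
    if not pairs:
        log.warning("no sound-free BF stimulations: empty state epochs")
    return StateEpochs(epochs)


def stimulus_free_sync_intervals(
    session: Session, desync_len_s: float, margin_s: float = 1.0
) -> list[tuple[float, float]]:
    """Stimulus-free synchronized periods (for UP-state detection).

    Removes, from the whole session, every presumed-desynchronized period
    (bf_on to bf_off + ``desync_len_s`` + 2 s settle) and a margin around
    every sound event.
    """
    t_end = session.lfp.t0 + session.lfp.duration
    cuts = []
    for on, off in session.events.bf_pairs():
        cuts.append((on - margin_s, off + desync_len_s + 2.0))
    df = session.events.df
    for row in df[df["kind"] == "click"].itertuples(index=False):
        cuts.append((row.time_s - margin_s, row.time_s + 1.0))
    on_t = df[df["kind"] == "train_onset"]["time_s"].to_numpy()
    off_t = df[df["kind"] == "train_offset"]["time_s"].to_numpy()
    for a, b in zip(on_t, off_t):
        cuts.append((a - margin_s, b + 1.0))
    cuts.sort()
    free = []
    cursor = 0.0
    for a, b in cuts:
        if a > cursor:
            free.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < t_end:
        free.append((cursor, t_end))
    return [(a, b) for a, b in free if b - a > 0.5]


def _rate_in_intervals(spike_times, intervals) -> float:
    total_t = sum(b - a for a, b in intervals)
    if total_t <= 0:
        return float("nan")
    t = np.asarray(spike_times)
    n = sum(int(np.searchsorted(t, b) - np.searchsorted(t, a))
            for a, b in intervals)
    return n / total_t


def _segments(lfp, intervals) -> list[np.ndarray]:
    segs = []
    for a, b in intervals:
        i0 = max(0, int(round((a - lfp.t0) * lfp.fs)))
        i1 = min(lfp.n_samples, int(round((b - lfp.t0) * lfp.fs)))
        if i1 - i0 >= lfp.fs:
            segs.append(lfp.samples[:, i0:i1])
    return segs


def _mean(vals) -> float:
    arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
    return float(arr.mean()) if arr.size else float("nan")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: RunConfig,
    out_dir: str | Path | None = None,
    session: Session | None = None,
    ground_truth: GroundTruth | None = None,
    write_outputs: bool = True,
) -> dict:
    """Execute all stages in dependency order; return the report dict.

    ``session`` may be supplied directly (it bypasses both simulation and
    reading ``config.session_dir``).  When ``out_dir`` is given, stage
    outputs (epochs.tsv, band_power.tsv, onset_stats.tsv, correlations.tsv,
    vs.tsv, ...) and report.json are written there.
    """
    logging.basicConfig(level=config.log_level)
    cfg = config
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    # --- stage: session -------------------------------------------------
    gt: GroundTruth | None = ground_truth
    if session is None:
        if cfg.simulate:
            session, gt = simulate_session(cfg.sim, cfg.seed)
            log.info("simulated session: %.0f s, %d units",
                     session.lfp.duration, len(session.units))
        elif cfg.session_dir:
            session = read_session(cfg.session_dir)
        else:
            raise StageError("session", "no session_dir and simulate=False")

    # --- stage: unit screening ------------------------------------------
    units = filter_units(session.units, cfg.min_quality)
    log.info("unit screening: %d/%d units pass quality >= %g",
             len(units), len(session.units), cfg.min_quality)
    if not units:
        raise StageError("screening", "no units pass the quality threshold")

    # --- stage: preprocess ----------------------------------------------
    try:
        lfp = spectral.preprocess_lfp(session.lfp)
    except ValueError as e:
        raise StageError("preprocess", str(e)) from e

    # --- stage: csd / depth alignment -----------------------------------
    stages = set(cfg.stages)
    if "csd" not in stages:
        raise StageError("classify", "missing recipient channel: csd stage disabled")
    click_times = session.events.times_of("click")
    try:
        csd = laminar.compute_csd(laminar.smooth_depth(lfp))
        recipient = laminar.find_recipient_channel(
            csd, click_times, cfg.sink_window_ms)
    except ValueError as e:
        raise StageError("csd", str(e)) from e
    report["recipient_channel"] = recipient
    log.info("recipient channel: %d", recipient)

    # --- stage: classify -------------------------------------------------
    for u in units:
        u.depth_channel = laminar.estimate_unit_depth(u.mean_waveform)
    ac_units = [u for u in units if u.area == "AC"]
    laminar.assign_relative_depths(ac_units, recipient, session.lfp.spacing_um)
    unit_classes.classify_units(units)
    classes = {u.unit_id: u.cell_class for u in units}
    areas = {u.unit_id: u.area for u in units}
    ac_ids = [u.unit_id for u in ac_units]
    report["n_units"] = {
        "total": len(session.units), "analyzed": len(units),
        "AC": len(ac_ids), "MGB": len(units) - len(ac_ids),
    }
    report["class_counts"] = dict(sorted(pd.Series(
        [u.cell_class for u in units]).value_counts().items()))

    # --- stage: state epochs ---------------------------------------------
    if "states" not in stages:
        raise StageError("evoked", "missing epochs: states stage disabled")
    spont_epochs = spontaneous_state_epochs(
        session, cfg.spont_window_s, cfg.desync_len_s)
    sync_w = spont_epochs.intervals("synchronized")
    desync_w = spont_epochs.intervals("desynchronized")
    trial_states = states.assign_trial_states(session.events, ("click",))
    train_states = states.assign_trial_states(session.events, ("train_onset",))
    if not sync_w or not desync_w:
        raise StageError("states", "missing epochs: no BF stimulations found")

    # --- stage: UP detection ---------------------------------------------
    mua = states.compute_mua(
        session.spikes, ac_ids, t_start=0.0,
        t_end=session.lfp.t0 + session.lfp.duration,
        bin_ms=cfg.mua_bin_ms, kernel_ms=cfg.mua_kernel_ms)
    spont_sync = stimulus_free_sync_intervals(session, cfg.desync_len_s)
    mask = states.mask_from_intervals(mua, spont_sync)
    up_epochs, theta = states.detect_up_states(
        mua, mask, strict_above=cfg.strict_up_criterion)
    up_ivals = up_epochs.intervals("up_state")
    report["up_states"] = {
        "n_detected": len(up_ivals),
        "threshold": theta,
        "total_up_s": round(sum(b - a for a, b in up_ivals), 3),
    }
    log.info("UP states: %d detected (threshold %.4g)", len(up_ivals), theta)

    # --- stage: spontaneous rates ----------------------------------------
    per_unit_rows = []
    for u in units:
        t = session.spikes[u.unit_id] if u.unit_id in session.spikes else np.array([])
        r_s = _rate_in_intervals(t, sync_w)
        r_d = _rate_in_intervals(t, desync_w)
        r_up = _rate_in_intervals(t, up_ivals) if up_ivals else float("nan")
        mi = (response_stats.modulation_index(r_s, r_d)
              if r_s + r_d > 0 else float("nan"))
        mi_up = (response_stats.up_vs_desync_index(r_up, r_d)
                 if np.isfinite(r_up) and r_up + r_d > 0 else float("nan"))
        per_unit_rows.append({
            "unit_id": u.unit_id, "cell_class": u.cell_class, "area": u.area,
            "rate_sync": r_s, "rate_desync": r_d, "rate_up": r_up,
            "mi_rate": mi, "mi_up_vs_desync": mi_up,
        })
    spont_df = pd.DataFrame(per_unit_rows)
    by_class = spont_df.groupby("cell_class")
    report["spont_rate_mi"] = {
        c: {"mean": _mean(g["mi_rate"]), "n": int(len(g))}
        for c, g in by_class}
    report["up_vs_desync_mi"] = {
        c: _mean(g["mi_up_vs_desync"]) for c, g in by_class}

    # --- stage: spectra ---------------------------------------------------
    seg_by_state = {
        "synchronized": _segments(lfp, sync_w),
        "desynchronized": _segments(lfp, desync_w),
    }
    bp = spectral.band_power_table(
        seg_by_state, lfp.fs, method=cfg.psd_method, nw=cfg.psd_nw)
    bp_mi = spectral.band_power_state_mi(bp)
    n_ch = lfp.n_channels
    deep_ch = [c for c in range(n_ch)
               if (recipient - c) * session.lfp.spacing_um <= cfg.deep_depth_um]
    sup_ch = [c for c in range(n_ch) if c <= recipient]

    def _band_mi(chs, band):
        sel = bp_mi[(bp_mi["band"] == band) & (bp_mi["channel"].isin(chs))]
        return _mean(sel["mi"])

    report["band_power_mi"] = {
        "deep_delta": _band_mi(deep_ch, "delta"),
        "superficial_delta": _band_mi(sup_ch, "delta"),
        "deep_low_gamma": _band_mi(deep_ch, "low_gamma"),
        "superficial_low_gamma": _band_mi(sup_ch, "low_gamma"),
    }

    si_channel = (cfg.state_index_channel if cfg.state_index_channel is not None
                  else min(n_ch - 1, recipient + 8))
    si_t, si_v = spectral.state_index(lfp, si_channel)
    report["state_index_channel"] = si_channel

    # --- stage: evoked ----------------------------------------------------
    counts_by_unit = {}
    for u in units:
        t = session.spikes[u.unit_id]
        counts_by_unit[u.unit_id] = response_stats.trial_counts(
            t, trial_states, cfg.onset_window_ms, unit_id=u.unit_id)
    responsive = set(response_stats.responsive_filter(counts_by_unit))
    onset_rows = []
    for uid in sorted(responsive):
        per_state = counts_by_unit[uid]
        rec = {"unit_id": uid, "cell_class": classes[uid], "area": areas[uid]}
        for state, tc in per_state.items():
            short = "sync" if state == "synchronized" else "desync"
            rec[f"mu_{short}"] = tc.mean
            rec[f"var_{short}"] = tc.variance
            rec[f"fano_{short}"] = tc.fano
        rec["mi_mu"] = response_stats.modulation_index(
            rec["mu_sync"], rec["mu_desync"])
        rec["mi_var"] = (response_stats.modulation_index(
            rec["var_sync"], rec["var_desync"])
            if rec["var_sync"] + rec["var_desync"] > 0 else float("nan"))
        rec["mi_fano"] = (response_stats.modulation_index(
            rec["fano_sync"], rec["fano_desync"])
            if np.isfinite(rec["fano_sync"]) and np.isfinite(rec["fano_desync"])
            else float("nan"))
        onset_rows.append(rec)
    onset_df = pd.DataFrame(onset_rows)
    report["n_responsive"] = {
        "AC": int((onset_df["area"] == "AC").sum()) if len(onset_df) else 0,
        "MGB": int((onset_df["area"] == "MGB").sum()) if len(onset_df) else 0,
    }

    def _onset_summary(df):
        return {"mi_mu": _mean(df["mi_mu"]), "mi_var": _mean(df["mi_var"]),
                "mi_fano": _mean(df["mi_fano"]), "n": int(len(df))}

    report["onset_mi_by_area"] = {
        a: _onset_summary(g) for a, g in onset_df.groupby("area")}
    report["onset_mi_by_class"] = {
        c: _onset_summary(g) for c, g in onset_df.groupby("cell_class")}

    # mean spike time (late window), responsive units, per area
    mst_rows = []
    for uid in sorted(responsive):
        t = session.spikes[uid]
        m_s = response_stats.mean_spike_time(
            t, trial_states["synchronized"], cfg.late_window_ms)
        m_d = response_stats.mean_spike_time(
            t, trial_states["desynchronized"], cfg.late_window_ms)
        mst_rows.append({"unit_id": uid, "area": areas[uid],
                         "cell_class": classes[uid],
                         "mst_sync": m_s, "mst_desync": m_d,
                         "delta": m_d - m_s})
    mst_df = pd.DataFrame(mst_rows)
    report["mean_spike_time_ms"] = {
        a: {"sync": _mean(g["mst_sync"]), "desync": _mean(g["mst_desync"]),
            "delta": _mean(g["delta"]), "n": int(len(g))}
        for a, g in mst_df.groupby("area")}

    # normalized PSTH peak latencies (population display support)
    psth_rows = []
    psth_profiles = []
    for uid in sorted(responsive):
        for state in ("synchronized", "desynchronized"):
            try:
                p = response_stats.normalized_psth(
                    session.spikes[uid], trial_states[state],
                    state=state, unit_id=uid)
            except ValueError:
                continue
            psth_rows.append({"unit_id": uid, "state": state,
                              "peak_latency_ms": p.peak_latency_ms})
            psth_profiles.append(p.profile)

    # --- stage: correlations ----------------------------------------------
    trains_all = {u.unit_id: session.spikes[u.unit_id] for u in units}
    corr = {}
    for state, windows in (("sync", sync_w), ("desync", desync_w)):
        cm = response_stats.correlation_matrix(trains_all, windows)
        cm["pair_type"] = [
            _pair_type(areas[i], classes[i], areas[j], classes[j])
            for i, j in zip(cm["unit_i"], cm["unit_j"])]
        corr[state] = cm
    corr_summary: dict = {}
    for state, cm in corr.items():
        for ptype, g in cm.groupby("pair_type"):
            corr_summary.setdefault(ptype, {})[state] = _mean(g["r"])
    report["correlations"] = {
        k: corr_summary[k] for k in sorted(corr_summary)}

    # --- stage: phase locking ---------------------------------------------
    samples = []
    onsets_df = session.events.of_kind("train_onset")
    for u in units:
        t = session.spikes[u.unit_id]
        for state_label, bkind in (("synchronized", "no_stim"),
                                   ("desynchronized", "stim")):
            sel = onsets_df[onsets_df["block_kind"] == bkind]
            for hz, g in sel.groupby("train_hz"):
                samples.append(circular.extract_phases(
                    t, g["time_s"].to_numpy(), int(hz),
                    exclusion_ms=cfg.exclusion_ms, unit_id=u.unit_id,
                    state=state_label))
    vs_per_unit, vs_fractions = circular.vs_state_summary(
        samples, alpha=cfg.rayleigh_alpha, classes=classes)
    if len(vs_per_unit):
        vs_by_class = vs_per_unit.groupby("cell_class")["vs_mi"].mean()
        report["vs_mi_by_class"] = {c: float(v) for c, v in vs_by_class.items()}
        report["delta_fraction_by_class"] = {
            c: _mean(g["delta_fraction"])
            for c, g in vs_fractions.groupby("cell_class")}
    else:
        report["vs_mi_by_class"] = {}
        report["delta_fraction_by_class"] = {}

    # --- ground-truth annotations (simulation runs only) -------------------
    if gt is not None:
        report["up_state_recovery"] = _up_recovery(gt, up_ivals, spont_sync)

    # --- outputs ----------------------------------------------------------
    if out is not None and write_outputs:
        _write_tsv(out / "epochs.tsv",
                   pd.DataFrame([{"t_start": a, "t_end": b, "label": lab}
                                 for a, b, lab in
                                 spont_epochs.extend(up_epochs)]))
        _write_tsv(out / "units_classified.tsv", pd.DataFrame([
            {"unit_id": u.unit_id, "area": u.area, "quality": u.quality,
             "depth_channel": u.depth_channel,
             "relative_depth_um": u.relative_depth_um,
             "trough_to_peak_ms": u.trough_to_peak_ms,
             "cell_class": u.cell_class} for u in units]))
        _write_tsv(out / "spont_rates.tsv", spont_df)
        _write_tsv(out / "band_power.tsv", bp)
        _write_tsv(out / "band_power_mi.tsv", bp_mi)
        _write_tsv(out / "state_index.tsv",
                   pd.DataFrame({"time_s": si_t, "power_le7hz": si_v}))
        _write_tsv(out / "onset_stats.tsv", onset_df)
        _write_tsv(out / "mean_spike_time.tsv", mst_df)
        _write_tsv(out / "psth_peaks.tsv", pd.DataFrame(psth_rows))
        if psth_profiles:
            np.asarray(psth_profiles, dtype=np.float32).tofile(
                out / "psth_norm.bin")
        _write_tsv(out / "correlations.tsv",
                   pd.concat([cm.assign(state=s) for s, cm in corr.items()],
                             ignore_index=True))
        _write_tsv(out / "vs.tsv", vs_per_unit)
        _write_tsv(out / "fraction_modulated.tsv", vs_fractions)
        (out / "resolved_config.json").write_text(
            json.dumps(cfg.to_dict(), indent=1, sort_keys=True, default=list))
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float))
    return report


def _pair_type(area_i, cls_i, area_j, cls_j) -> str:
    if area_i == "AC" and area_j == "AC":
        kinds = sorted("NS" if c == "NS" else "BS" for c in (cls_i, cls_j))
        return f"AC-AC:{kinds[0]}-{kinds[1]}"
    if area_i == "MGB" and area_j == "MGB":
        return "MGB-MGB"
    ac_cls = cls_i if area_i == "AC" else cls_j
    kind = "NS" if ac_cls == "NS" else "BS"
    return f"AC-MGB:{kind}-MGB"


def _up_recovery(gt: GroundTruth, detected: list[tuple[float, float]],
                 searchable: list[tuple[float, float]] | None = None,
                 min_len_s: float = 0.3) -> dict:
    """Fraction of true UP intervals >= 300 ms with a detected onset nearby.

    ``searchable`` restricts scoring to true UP intervals inside the
    spontaneous mask actually searched by the detector (with room for the
    100 ms pre-window).
    """
    truths = [(a, b) for a, b in gt.up_intervals if b - a >= min_len_s]
    if searchable is not None:
        truths = [(a, b) for a, b in truths
                  if any(a - 0.15 >= s0 and b <= s1 for s0, s1 in searchable)]
    if not truths:
        return {"n_true": 0, "fraction_detected": float("nan"),
                "median_onset_error_ms": float("nan")}
    onsets = np.asarray([a for a, _ in detected])
    errs = []
    n_hit = 0
    for a, b in truths:
        if onsets.size == 0:
            continue
        d = onsets - a
        near = d[(d > -0.05) & (d < (b - a))]
        if near.size:
            n_hit += 1
            errs.append(np.abs(near).min() * 1e3)
    return {
        "n_true": len(truths),
        "fraction_detected": n_hit / len(truths),
        "median_onset_error_ms": float(np.median(errs)) if errs else float("nan"),
    }


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
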
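"""Domain types and session I/O.

A *session* bundles everything one laminar recording produces: a multichannel
LFP, spike-sorted unit spike times, per-unit metadata (mean waveforms, depth,
cell class, isolation quality) and an event table (basal-forebrain stimulation
pulses, single clicks, click-train onsets).  All times share one session clock
in seconds; LFP sample ``k`` is at ``t0 + k / fs``.  Channel index 0 is the
most superficial recording site and indices increase with depth.

On-disk format (one directory per session): ``lfp.bin`` (row-major float32,
channels x samples) with sidecar ``lfp.json``; ``spikes.tsv``;
``waveforms.bin`` + ``waveforms.json``; ``units.tsv``; ``events.tsv``.  Text
files are UTF-8, tab-separated, with a header line.  Signals are float32 on
disk, float64 in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CELL_CLASSES = ("NS", "BS1", "BS2", "BS3", "BS4", "MGB", "unclassified")
EVENT_KINDS = ("bf_on", "bf_off", "click", "train_onset", "train_offset")
TRAIN_FREQUENCIES = (4, 8, 16, 32, 64)
STATE_LABELS = ("synchronized", "desynchronized", "up_state")

#: isolation-quality threshold below which units are discarded
DEFAULT_MIN_QUALITY = 20.0


class ValidationError(ValueError):
    """An object violates a session invariant."""


class MissingComponentError(FileNotFoundError):
    """A canonical session file is absent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LaminarLFP:
    """Multichannel laminar local field potential.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_timepoints)
        Potential in microvolts.
    fs : float
        Sampling rate, Hz.
    spacing_um : float
        Inter-channel spacing in micrometres (50 for the probes modelled here).
    channel0_position : str
        Fixes the orientation convention: index 0 is the most superficial
        channel.
    t0 : float
        Session time of the first sample, seconds.
    """

    samples: np.ndarray
    fs: float
    spacing_um: float = 50.0
    channel0_position: str = "superficial"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("LFP samples must be 2-D (channels x time)")
        if self.n_channels < 3:
            raise ValidationError("LFP needs at least 3 channels")
        if not self.fs > 0:
            raise ValidationError("LFP sampling rate must be positive")
        if not self.spacing_um > 0:
            raise ValidationError("channel spacing must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "LaminarLFP":
        return replace(self, **kw)


class SpikeTrainSet:
    """Per-unit sorted spike times (seconds, session clock)."""

    def __init__(self, trains: Mapping[int, np.ndarray]):
        self._trains: dict[int, np.ndarray] = {}
        for unit_id, times in trains.items():
            t = np.asarray(times, dtype=np.float64)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"unit {unit_id}: non-increasing spike times"
                )
            if t.size and t[0] < 0:
                raise ValidationError(f"unit {unit_id}: negative spike time")
            self._trains[int(unit_id)] = t

    def __getitem__(self, unit_id: int) -> np.ndarray:
        return self._trains[unit_id]

    def __contains__(self, unit_id: int) -> bool:
        return unit_id in self._trains

    def __len__(self) -> int:
        return len(self._trains)

    def __iter__(self):
        return iter(self._trains)

    def items(self):
        return self._trains.items()

    def unit_ids(self) -> list[int]:
        return sorted(self._trains)

    def n_spikes(self) -> int:
        return sum(t.size for t in self._trains.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        if set(self._trains) != set(other._trains):
            return False
        return all(
            np.array_equal(self._trains[u], other._trains[u])
            for u in self._trains
        )


@dataclass
class UnitMeta:
    """Per-unit metadata attached to one spike-sorted unit.

    ``relative_depth_um`` is positive toward the pia with 0 at the thalamic
    recipient layer; ``depth_channel`` is the channel of the somatic estimate
    (site of maximum trough-to-peak waveform amplitude).  ``quality`` is an
    isolation-distance-like scalar used for unit screening.
    """

    unit_id: int
    mean_waveform: np.ndarray  # (n_channels, n_wave_samples), microvolts
    wave_fs: float
    trough_to_peak_ms: float | None = None
    depth_channel: int | None = None
    relative_depth_um: float | None = None
    cell_class: str = "unclassified"
    quality: float = 0.0
    area: str = "AC"  # AC or MGB

    def __post_init__(self) -> None:
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=np.float64)
        if self.mean_waveform.ndim != 2:
            raise ValidationError("mean_waveform must be 2-D")
        if self.trough_to_peak_ms is not None and not self.trough_to_peak_ms > 0:
            raise ValidationError("trough_to_peak_ms must be positive")
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(f"unknown cell class {self.cell_class!r}")
        if self.quality < 0:
            raise ValidationError("quality must be non-negative")
        if self.area not in ("AC", "MGB"):
            raise ValidationError(f"unknown area {self.area!r}")


@dataclass
class EventTable:
    """Timestamped stimulation / stimulus events.

    Columns: ``time_s, kind, level_db, train_hz, block_id, block_kind``.
    ``kind`` is one of bf_on / bf_off / click / train_onset / train_offset;
    ``block_kind`` is ``stim`` (trials preceded by BF stimulation) or
    ``no_stim``.
    """

    df: pd.DataFrame

    COLUMNS = ("time_s", "kind", "level_db", "train_hz", "block_id", "block_kind")

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if np.any(np.diff(df["time_s"].to_numpy()) < 0):
            raise ValidationError("event times must be non-decreasing")
        bad = set(df["kind"]) - set(EVENT_KINDS)
        if bad:
            raise ValidationError(f"unknown event kinds {sorted(bad)}")
        # every bf_on needs a matching later bf_off
        depth = 0
        for kind in df["kind"]:
            if kind == "bf_on":
                if depth:
                    raise ValidationError("nested bf_on without bf_off")
                depth += 1
            elif kind == "bf_off":
                if not depth:
                    raise ValidationError("bf_off without preceding bf_on")
                depth -= 1
        if depth:
            raise ValidationError("bf_on without matching bf_off")
        onsets = df[df["kind"] == "train_onset"]
        if onsets["train_hz"].isna().any():
            raise ValidationError("train_onset events must carry train_hz")
        bad_hz = set(onsets["train_hz"].dropna().astype(int)) - set(TRAIN_FREQUENCIES)
        if bad_hz:
            raise ValidationError(f"unsupported train frequencies {sorted(bad_hz)}")
        self.df = df

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind]

    def times_of(self, kind: str) -> np.ndarray:
        return self.of_kind(kind)["time_s"].to_numpy()

    def bf_pairs(self) -> list[tuple[float, float]]:
        """Matched (bf_on, bf_off) time pairs, in order."""
        ons = self.times_of("bf_on")
        offs = self.times_of("bf_off")
        return list(zip(ons, offs))

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.df.equals(other.df)


@dataclass
class StateEpochs:
    """Labelled time intervals: synchronized / desynchronized / up_state."""

    epochs: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t0, t1, label in self.epochs:
            if not t1 > t0:
                raise ValidationError(f"epoch ({t0}, {t1}) has non-positive length")
            if label not in STATE_LABELS:
                raise ValidationError(f"unknown epoch label {label!r}")
        for label in STATE_LABELS:
            ivals = sorted(self.intervals(label))
            for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise ValidationError(
                        f"overlapping {label} epochs ({a0},{a1}) and ({b0},{b1})"
                    )

    def intervals(self, label: str) -> list[tuple[float, float]]:
        return [(t0, t1) for t0, t1, lab in self.epochs if lab == label]

    def total_duration(self, label: str) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.intervals(label)))

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def extend(self, other: "StateEpochs") -> "StateEpochs":
        return StateEpochs(self.epochs + other.epochs)


@dataclass
class Session:
    """One recording session: LFP + spikes + unit metadata + events."""

    lfp: LaminarLFP
    spikes: SpikeTrainSet
    units: list[UnitMeta]
    events: EventTable

    def unit_map(self) -> dict[int, UnitMeta]:
        return {u.unit_id: u for u in self.units}

    def units_in(self, area: str) -> list[UnitMeta]:
        return [u for u in self.units if u.area == area]


# ---------------------------------------------------------------------------
# unit screening
# ---------------------------------------------------------------------------

def filter_units(
    units: Iterable[UnitMeta], min_quality: float = DEFAULT_MIN_QUALITY
) -> list[UnitMeta]:
    """Keep units whose isolation quality is at least ``min_quality``.

    The inclusive threshold mirrors the standard isolation-distance screen
    (units with value >= 20 retained).  Order is preserved.
    """
    return [u for u in units if u.quality >= min_quality]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _fmt_float(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return ""
    return repr(float(x))


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session to ``path`` in the canonical directory format."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    lfp = session.lfp
    lfp.samples.astype(np.float32).tofile(path / "lfp.bin")
    (path / "lfp.json").write_text(json.dumps({
        "fs": lfp.fs,
        "n_channels": lfp.n_channels,
        "spacing_um": lfp.spacing_um,
        "channel0_position": lfp.channel0_position,
        "t0": lfp.t0,
    }, indent=1))

    with open(path / "spikes.tsv", "w", encoding="utf-8") as fh:
        fh.write("unit_id\ttime_s\n")
        for unit_id in session.spikes.unit_ids():
            for t in session.spikes[unit_id]:
                fh.write(f"{unit_id}\t{float(t)!r}\n")

    units = session.units
    order = [u.unit_id for u in units]
    if units:
        wf = np.stack([u.mean_waveform for u in units])
        wf.astype(np.float32).tofile(path / "waveforms.bin")
        wave_fs = units[0].wave_fs
        n_ch, n_ws = units[0].mean_waveform.shape
    else:
        (path / "waveforms.bin").write_bytes(b"")
        wave_fs, n_ch, n_ws = 0.0, 0, 0
    (path / "waveforms.json").write_text(json.dumps({
        "unit_order": order,
        "wave_fs": wave_fs,
        "n_channels": n_ch,
        "n_wave_samples": n_ws,
    }, indent=1))

    with open(path / "units.tsv", "w", encoding="utf-8") as fh:
        fh.write("unit_id\tquality\tcell_class\tarea\ttrough_to_peak_ms\t"
                 "depth_channel\trelative_depth_um\n")
        for u in units:
            fh.write("\t".join([
                str(u.unit_id),
                _fmt_float(u.quality),
                u.cell_class,
                u.area,
                _fmt_float(u.trough_to_peak_ms),
                "" if u.depth_channel is None else str(u.depth_channel),
                _fmt_float(u.relative_depth_um),
            ]) + "\n")

    ev = session.events.df
    with open(path / "events.tsv", "w", encoding="utf-8") as fh:
        fh.write("\t".join(EventTable.COLUMNS) + "\n")
        for row in ev.itertuples(index=False):
            fh.write("\t".join([
                repr(float(row.time_s)),
                row.kind,
                _fmt_float(row.level_db),
                "" if pd.isna(row.train_hz) else str(int(row.train_hz)),
                str(row.block_id),
                str(row.block_kind),
            ]) + "\n")

    return path


def _require(path: Path) -> Path:
    if not path.exists():
        raise MissingComponentError(f"missing component: {path.name}")
    return path


def read_session(path: str | Path) -> Session:
    """Read a session directory; every invariant is checked on load."""
    path = Path(path)

    meta = json.loads(_require(path / "lfp.json").read_text())
    raw = np.fromfile(_require(path / "lfp.bin"), dtype=np.float32)
    samples = raw.reshape(meta["n_channels"], -1).astype(np.float64)
    lfp = LaminarLFP(
        samples=samples,
        fs=meta["fs"],
        spacing_um=meta["spacing_um"],
        channel0_position=meta.get("channel0_position", "superficial"),
        t0=meta.get("t0", 0.0),
    )

    spk = pd.read_csv(_require(path / "spikes.tsv"), sep="\t",
                      float_precision="round_trip")
    trains: dict[int, list[float]] = {}
    for unit_id, t in zip(spk["unit_id"], spk["time_s"]):
        trains.setdefault(int(unit_id), []).append(float(t))
    spikes = SpikeTrainSet({u: np.asarray(ts) for u, ts in trains.items()})

    wmeta = json.loads(_require(path / "waveforms.json").read_text())
    order = wmeta["unit_order"]
    if order:
        wf = np.fromfile(_require(path / "waveforms.bin"), dtype=np.float32)
        wf = wf.reshape(len(order), wmeta["n_channels"], wmeta["n_wave_samples"])
    else:
        _require(path / "waveforms.bin")
        wf = np.zeros((0, 0, 0), dtype=np.float32)

    udf = pd.read_csv(_require(path / "units.tsv"), sep="\t",
                      float_precision="round_trip")
    by_id = {int(r.unit_id): r for r in udf.itertuples(index=False)}
    units = []
    for i, unit_id in enumerate(order):
        r = by_id[int(unit_id)]
        units.append(UnitMeta(
            unit_id=int(unit_id),
            mean_waveform=wf[i].astype(np.float64),
            wave_fs=wmeta["wave_fs"],
            trough_to_peak_ms=None if pd.isna(r.trough_to_peak_ms) else float(r.trough_to_peak_ms),
            depth_channel=None if pd.isna(r.depth_channel) else int(r.depth_channel),
            relative_depth_um=None if pd.isna(r.relative_depth_um) else float(r.relative_depth_um),
            cell_class=r.cell_class,
            quality=float(r.quality),
            area=r.area,
        ))

    edf = pd.read_csv(
        _require(path / "events.tsv"), sep="\t",
        dtype={"kind": str, "block_id": str, "block_kind": str},
        float_precision="round_trip",
    )
    edf["level_db"] = pd.to_numeric(edf["level_db"], errors="coerce")
    edf["train_hz"] = pd.to_numeric(edf["train_hz"], errors="coerce")
    events = EventTable(edf)

    return Session(lfp=lfp, spikes=spikes, units=units, events=events)
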
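"""Data model and file I/O shared by every pipeline stage.

The on-disk interchange is deliberately plain: EEG in EDF+ (16-bit), an
events sidecar as tab-separated text, and a sensor layout table with
Cartesian positions in centimetres.  Everything else (cluster results,
combined effects, reports) is TSV or JSON.

Conventions
-----------
* Signals are stored channels x samples in microvolts (uV).
* Sample indexing is 0-based; epoch windows are half-open in samples.
* Latencies are reported in milliseconds.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger("herpipeline")

__all__ = [
    "Group",
    "BlockType",
    "Condition",
    "SensorLayout",
    "AuditoryEvent",
    "Recording",
    "NeighborGraph",
    "FormatError",
    "ConsistencyError",
    "build_neighbor_graph",
    "load_recording",
    "write_recording",
    "write_edf",
    "read_edf",
    "read_events_tsv",
    "write_events_tsv",
    "read_layout_tsv",
    "write_layout_tsv",
    "save_table",
    "read_table",
]


class FormatError(ValueError):
    """Malformed file content (header, columns, enum values)."""


class ConsistencyError(ValueError):
    """Files disagree with each other or with the recording geometry."""


class Group(str, Enum):
    MCS = "MCS"
    UWS = "UWS"
    CONTROL = "CONTROL"
    UNKNOWN = "UNKNOWN"


class BlockType(str, Enum):
    XX = "XX"
    XY = "XY"


class Condition(str, Enum):
    """Local/global x standard/deviant trial taxonomy.

    LSGS: local standard, global standard (frequent in XX blocks)
    LDGD: local deviant, global deviant (rare in XX blocks)
    LDGS: local deviant, global standard (frequent in XY blocks)
    LSGD: local standard, global deviant (rare in XY blocks)
    """

    LSGS = "LSGS"
    LSGD = "LSGD"
    LDGS = "LDGS"
    LDGD = "LDGD"

    @property
    def local_deviant(self) -> bool:
        return self in (Condition.LDGS, Condition.LDGD)

    @property
    def global_deviant(self) -> bool:
        return self in (Condition.LSGD, Condition.LDGD)


@dataclass
class SensorLayout:
    """Channel names and 3-D positions (cm)."""

    names: list[str]
    positions: np.ndarray  # (n_channels, 3) in cm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise FormatError("duplicate channel names in layout")
        if self.positions.shape != (len(self.names), 3):
            raise FormatError("layout positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("layout positions must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: list[str]) -> "SensorLayout":
        idx = [self.index(n) for n in names]
        return SensorLayout(list(names), self.positions[idx])


@dataclass(frozen=True)
class AuditoryEvent:
    """One sound onset of a five-sound local-global trial."""

    onset_sample: int
    trial_id: int
    sound_index: int  # 1..5
    block_type: BlockType
    condition: Condition

    def __post_init__(self) -> None:
        if not 1 <= self.sound_index <= 5:
            raise FormatError(f"sound_index must be 1..5, got {self.sound_index}")


@dataclass
class Recording:
    """One subject's EEG with layout, events and provenance."""

    subject_id: str
    group: Group
    eeg: np.ndarray  # (n_channels, n_samples) in uV
    fs: float
    layout: SensorLayout
    events: list[AuditoryEvent] = field(default_factory=list)
    preproc_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg)
        if self.eeg.dtype.kind != "f":
            self.eeg = self.eeg.astype(float)
        if self.eeg.ndim != 2:
            raise FormatError("eeg must be channels x samples")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        if self.eeg.shape[0] != len(self.layout):
            raise ConsistencyError(
                f"{self.eeg.shape[0]} EEG channels but layout has {len(self.layout)}"
            )
        n = self.eeg.shape[1]
        for ev in self.events:
            if not 0 <= ev.onset_sample < n:
                raise ConsistencyError(
                    f"event at sample {ev.onset_sample} outside recording "
                    f"of {n} samples"
                )
        _validate_trials(self.events)

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[0]

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    def log_step(self, step: str) -> None:
        stamp = datetime.now().isoformat(timespec="seconds")
        self.preproc_log.append(f"[{stamp}] {step}")
        logger.info("%s: %s", self.subject_id, step)

    def copy_with(self, eeg: np.ndarray, layout: SensorLayout | None = None) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            group=self.group,
            eeg=eeg,
            fs=self.fs,
            layout=layout if layout is not None else self.layout,
            events=list(self.events),
            preproc_log=list(self.preproc_log),
        )


def _validate_trials(events: list[AuditoryEvent]) -> None:
    """Each trial has exactly five sounds, increasing onsets, one condition."""
    by_trial: dict[int, list[AuditoryEvent]] = {}
    for ev in events:
        by_trial.setdefault(ev.trial_id, []).append(ev)
    for tid, evs in by_trial.items():
        evs = sorted(evs, key=lambda e: e.sound_index)
        if [e.sound_index for e in evs] != [1, 2, 3, 4, 5]:
            raise ConsistencyError(f"trial {tid} does not have sounds 1..5")
        onsets = [e.onset_sample for e in evs]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ConsistencyError(f"trial {tid} onsets not strictly increasing")
        if len({e.condition for e in evs}) != 1:
            raise ConsistencyError(f"trial {tid} has mixed conditions")


# ---------------------------------------------------------------------------
# Neighbor graph
# ---------------------------------------------------------------------------

@dataclass
class NeighborGraph:
    """Sensor adjacency: channels within ``max_distance_cm`` of each other.

    The distance comparison is inclusive (<=), so two sensors exactly at the
    threshold are neighbours.
    """

    adjacency: list[set[int]]
    max_distance_cm: float

    def neighbors(self, idx: int) -> set[int]:
        return self.adjacency[idx]

    def __len__(self) -> int:
        return len(self.adjacency)


def build_neighbor_graph(layout: SensorLayout, max_distance_cm: float = 4.0) -> NeighborGraph:
    """Adjacency over sensors at Euclidean distance <= ``max_distance_cm``."""
    if len(layout) < 1:
        raise FormatError("layout must contain at least one channel")
    d = cdist(layout.positions, layout.positions)
    adj: list[set[int]] = []
    for i in range(len(layout)):
        nbr = set(np.nonzero(d[i] <= max_distance_cm)[0].tolist())
        nbr.discard(i)
        adj.append(nbr)
    return NeighborGraph(adjacency=adj, max_distance_cm=float(max_distance_cm))


# ---------------------------------------------------------------------------
# EDF writing / reading
#
# EDF (16-bit) is the one EEG interchange format every toolchain reads; no
# writer library is bundled with this stack, so a minimal one lives here.
# Physical min/max are set per channel from the observed range, which keeps
# the 16-bit quantisation error ~1e-4 of the signal span.  Recordings are
# padded with zeros to a whole number of 1-second data records (standard EDF
# behaviour); the events sidecar carries the true sample count.
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, data_uv: np.ndarray, fs: float, ch_names: list[str]) -> None:
    """Write channels x samples (uV) to an EDF file with 1-s data records."""
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_samp = data_uv.shape
    if len(ch_names) != n_ch:
        raise FormatError("channel name count mismatch")
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_samp] = data_uv

    dig_min, dig_max = -32768, 32767
    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    # guard degenerate (constant) channels
    flat = phys_max - phys_min < 1e-9
    phys_max = np.where(flat, phys_min + 1.0, phys_max)

    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(str(256 * (1 + n_ch)), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(str(n_rec), 8)
    header += _edf_field("1", 8)  # record duration (s)
    header += _edf_field(str(n_ch), 4)

    def per_channel(vals: list[str], width: int) -> bytes:
        return b"".join(_edf_field(v, width) for v in vals)

    header += per_channel([n[:16] for n in ch_names], 16)
    header += per_channel(["EEG"] * n_ch, 80)
    header += per_channel(["uV"] * n_ch, 8)
    header += per_channel([f"{v:.8g}"[:8] for v in phys_min], 8)
    header += per_channel([f"{v:.8g}"[:8] for v in phys_max], 8)
    header += per_channel([str(dig_min)] * n_ch, 8)
    header += per_channel([str(dig_max)] * n_ch, 8)
    header += per_channel([""] * n_ch, 80)
    header += per_channel([str(spr)] * n_ch, 8)
    header += per_channel([""] * n_ch, 32)

    # re-read physical min/max as the truncated ASCII to keep scaling exact
    pmin = np.array([float(f"{v:.8g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.8g}"[:8]) for v in phys_max])
    gain = (dig_max - dig_min) / (pmax - pmin)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            chunk = padded[:, r * spr:(r + 1) * spr]
            dig = np.round((chunk - pmin[:, None]) * gain[:, None] + dig_min)
            dig = np.clip(dig, dig_min, dig_max).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF/BrainVision file via mne; returns (uV data, fs, names)."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# TSV sidecars
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["onset_sample", "trial_id", "sound_index", "block_type", "condition"]


def write_events_tsv(path: str | Path, events: list[AuditoryEvent], fs: float,
                     n_samples: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {fs:g}\n")
        if n_samples is not None:
            fh.write(f"# n_samples: {n_samples}\n")
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for ev in events:
            fh.write(
                f"{ev.onset_sample}\t{ev.trial_id}\t{ev.sound_index}\t"
                f"{ev.block_type.value}\t{ev.condition.value}\n"
            )


def read_events_tsv(path: str | Path) -> tuple[list[AuditoryEvent], float | None, int | None]:
    """Returns (events, declared sampling rate or None, declared n_samples)."""
    fs_decl: float | None = None
    n_decl: int | None = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "sampling_rate_hz":
                fs_decl = float(val)
            elif key.strip() == "n_samples":
                n_decl = int(val)
    df = pd.read_csv(path, sep="\t", skiprows=header_lines)
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"events file missing columns: {sorted(missing)}")
    events = [
        AuditoryEvent(
            onset_sample=int(r.onset_sample),
            trial_id=int(r.trial_id),
            sound_index=int(r.sound_index),
            block_type=BlockType(r.block_type),
            condition=Condition(r.condition),
        )
        for r in df.itertuples()
    ]
    return events, fs_decl, n_decl


def write_layout_tsv(path: str | Path, layout: SensorLayout) -> None:
    with open(path, "w") as fh:
        fh.write("name\tx_cm\ty_cm\tz_cm\n")
        for name, (x, y, z) in zip(layout.names, layout.positions):
            fh.write(f"{name}\t{x:.17g}\t{y:.17g}\t{z:.17g}\n")


def read_layout_tsv(path: str | Path) -> SensorLayout:
    df = pd.read_csv(path, sep="\t")
    missing = {"name", "x_cm", "y_cm", "z_cm"} - set(df.columns)
    if missing:
        raise FormatError(f"layout file missing columns: {sorted(missing)}")
    return SensorLayout(
        names=[str(n) for n in df["name"]],
        positions=df[["x_cm", "y_cm", "z_cm"]].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Recording round trip
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, eeg_path: str | Path, events_path: str | Path,
                    layout_path: str | Path) -> None:
    write_edf(eeg_path, rec.eeg, rec.fs, rec.layout.names)
    write_events_tsv(events_path, rec.events, rec.fs, n_samples=rec.n_samples)
    write_layout_tsv(layout_path, rec.layout)


def load_recording(eeg_path: str | Path, events_path: str | Path,
                   layout_path: str | Path, subject_id: str | None = None,
                   group: Group = Group.UNKNOWN) -> Recording:
    """Read EEG + events + layout into a validated Recording.

    Raises :class:`ConsistencyError` on any disagreement between the three
    files (sampling rate, channel sets, event bounds) rather than silently
    dropping data.
    """
    data, fs, ch_names = read_edf(eeg_path)
    events, fs_decl, n_decl = read_events_tsv(events_path)
    if fs_decl is not None and abs(fs_decl - fs) > 1e-6:
        raise ConsistencyError(
            f"events sidecar declares {fs_decl} Hz but EEG file has {fs} Hz"
        )
    if n_decl is not None and n_decl <= data.shape[1]:
        data = data[:, :n_decl]  # strip EDF record padding
    layout = read_layout_tsv(layout_path)
    if set(layout.names) != set(ch_names):
        raise ConsistencyError(
            "layout channels do not match EEG channels: "
            f"only-in-layout={sorted(set(layout.names) - set(ch_names))[:5]}, "
            f"only-in-eeg={sorted(set(ch_names) - set(layout.names))[:5]}"
        )
    # order layout to the EEG channel order
    layout = layout.subset(ch_names)
    return Recording(
        subject_id=subject_id or Path(eeg_path).stem,
        group=group,
        eeg=data,
        fs=fs,
        layout=layout,
        events=events,
    )


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def save_table(records: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Tab-separated output with header; NaN serialised as 'NA'."""
    df = pd.DataFrame(records)
    if df.empty:
        raise FormatError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def save_json(obj: object, path: str | Path) -> None:
    class _Enc(json.JSONEncoder):
        def default(self, o):  # noqa: D102
            if isinstance(o, np.integer):
                return int(o)
            if isinstance(o, np.floating):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, Enum):
                return o.value
            return super().default(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Enc)
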
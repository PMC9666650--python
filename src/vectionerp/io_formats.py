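"""Reading and writing of continuous EEG (BrainVision triad) and behavioral tables.

The BrainVision format stores one recording as three files sharing a base name:
a text header (``.vhdr``), a text marker file (``.vmrk``) and a binary data file
(``.eeg``).  Only the multiplexed orientation is supported, with IEEE float32 or
signed int16 sample encodings; the vectorized orientation is rejected
explicitly.  All sample indices exposed by this package are 0-based (BrainVision
markers are 1-based on disk; the conversion happens here and nowhere else).

Behavioral trial tables are plain UTF-8 CSV with a header row.
"""

from __future__ import annotations

import configparser
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "Direction",
    "EventKind",
    "Event",
    "Recording",
    "TrialBehavior",
    "UnsupportedDialectError",
    "ValidationError",
    "read_brainvision",
    "write_brainvision",
    "read_behavior_table",
    "write_behavior_table",
    "write_results_table",
]


class ValidationError(ValueError):
    """Input violates a documented contract (bad label, bad range, bad shape)."""


class UnsupportedDialectError(ValueError):
    """BrainVision file uses an orientation/encoding outside the supported subset."""


class Condition(str, Enum):
    COHERENT = "coherent"
    INCOHERENT = "incoherent"
    NONE = "none"


class Direction(str, Enum):
    CW = "cw"
    CCW = "ccw"
    NONE = "none"


class EventKind(str, Enum):
    MOTION_ONSET = "motion_onset"
    MOTION_OFFSET = "motion_offset"
    VECTION_ONSET_CW = "vection_onset_cw"
    VECTION_ONSET_CCW = "vection_onset_ccw"
    VECTION_OFFSET_CW = "vection_offset_cw"
    VECTION_OFFSET_CCW = "vection_offset_ccw"
    TRIAL_START = "trial_start"


@dataclass(frozen=True)
class Event:
    """A trigger at a 0-based sample offset into the recording."""

    sample_index: int
    kind: EventKind
    condition: Condition = Condition.NONE
    direction: Direction = Direction.NONE

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValidationError(f"negative event sample index {self.sample_index}")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    ``data`` is channels x samples; ``channel_labels`` gives the ordered 10-10
    names (plus EOG bipolars); ``reference`` is an electrode label (FCz while
    recording) or ``"common_average"`` after re-referencing.
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    reference: str = "FCz"
    events: list[Event] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError("recording data must be channels x samples")
        if self.srate <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError("channel label count does not match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("duplicate channel labels")
        for ev in self.events:
            if not (0 <= ev.sample_index < self.data.shape[1]):
                raise ValidationError(
                    f"event sample {ev.sample_index} outside recording "
                    f"(n={self.data.shape[1]})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "Recording":
        out = replace(self, **kw)
        out.data = np.array(out.data, copy=True) if "data" not in kw else out.data
        return out


# ---------------------------------------------------------------------------
# BrainVision reading


def _parse_ini(text: str, path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    cp.optionxform = str  # keys are case-sensitive channel ids
    # header files start with a magic line that configparser cannot digest
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("Brain Vision"))
    try:
        cp.read_string(body)
    except configparser.Error as exc:  # pragma: no cover - malformed fixture
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    return cp


def _marker_description_map(code_map: dict | None):
    """Normalize a user code map {marker description -> Event kind spec}.

    Values may be an :class:`EventKind`, its string value, or a ``(kind,
    condition, direction)`` tuple of enums/strings.
    """
    out: dict[str, tuple[EventKind, Condition, Direction]] = {}
    for desc, val in (code_map or {}).items():
        if isinstance(val, (tuple, list)):
            kind, cond, direc = val
        else:
            kind, cond, direc = val, Condition.NONE, Direction.NONE
        out[desc] = (EventKind(kind), Condition(cond), Direction(direc))
    return out


def read_brainvision(header_path: str | Path, code_map: dict | None = None) -> Recording:
    """Read a BrainVision .vhdr/.vmrk/.eeg triad into a :class:`Recording`.

    Parameters
    ----------
    header_path
        Path to the ``.vhdr`` file.  The marker and binary files it names must
        live next to it.
    code_map
        Maps marker descriptions (e.g. ``"S  1"``) to event kinds; the trigger
        codes are site-specific so no mapping is hard-coded.  Unmapped stimulus
        markers are ignored.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    cp = _parse_ini(header_path.read_text(encoding="utf-8"), header_path)

    common = cp["Common Infos"]
    data_file = header_path.parent / common["DataFile"]
    marker_file = header_path.parent / common["MarkerFile"]
    for p in (data_file, marker_file):
        if not p.exists():
            raise FileNotFoundError(f"companion file named in header not found: {p}")

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise UnsupportedDialectError(
            f"only MULTIPLEXED orientation is supported, got {orientation}"
        )
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise UnsupportedDialectError("only BINARY data format is supported")

    n_channels = int(common["NumberOfChannels"])
    sampling_interval_us = float(common["SamplingInterval"])
    srate = 1e6 / sampling_interval_us

    binary_format = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if binary_format == "IEEE_FLOAT_32":
        dtype = np.dtype("<f4")
    elif binary_format == "INT_16":
        dtype = np.dtype("<i2")
    else:
        raise UnsupportedDialectError(f"unsupported binary format {binary_format}")

    labels: list[str] = []
    resolutions = np.ones(n_channels)
    for i in range(n_channels):
        entry = cp["Channel Infos"][f"Ch{i + 1}"]
        parts = entry.split(",")
        labels.append(parts[0])
        if len(parts) > 2 and parts[2] != "":
            resolutions[i] = float(parts[2])
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate channel labels in header")

    raw = np.fromfile(data_file, dtype=dtype)
    if raw.size % n_channels:
        raise ValidationError("binary data size not a multiple of the channel count")
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= resolutions[:, None]

    events = _read_markers(marker_file, code_map)
    return Recording(data=data, srate=srate, channel_labels=labels, events=events)


def _read_markers(marker_file: Path, code_map: dict | None) -> list[Event]:
    cp = _parse_ini(marker_file.read_text(encoding="utf-8"), marker_file)
    cmap = _marker_description_map(code_map)
    events: list[Event] = []
    infos = cp["Marker Infos"]
    for key in sorted(infos, key=lambda k: int(k[2:])):
        parts = infos[key].split(",")
        mtype, desc, position = parts[0], parts[1], int(parts[2])
        if mtype == "New Segment":
            continue
        if desc in cmap:
            kind, cond, direc = cmap[desc]
            events.append(
                Event(sample_index=position - 1, kind=kind, condition=cond, direction=direc)
            )
    return events


# ---------------------------------------------------------------------------
# BrainVision writing (multiplexed float32 dialect)


def write_brainvision(
    rec: Recording,
    base_path: str | Path,
    code_map: dict | None = None,
) -> tuple[Path, Path, Path]:
    """Write ``rec`` as a .vhdr/.vmrk/.eeg triad (multiplexed IEEE float32).

    ``code_map`` is the inverse of the reader's map: if given, events are
    written with the marker description whose mapped kind/condition/direction
    matches; otherwise a canonical description ``kind|condition|direction`` is
    used (which the reader accepts when handed the same canonical map built by
    :func:`canonical_code_map`).
    """
    base_path = Path(base_path)
    base_path.parent.mkdir(parents=True, exist_ok=True)
    vhdr, vmrk, eeg = (base_path.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    inv: dict[tuple, str] = {}
    for desc, val in _marker_description_map(code_map).items():
        inv[val] = desc

    interval_us = 1e6 / rec.srate
    interval_str = (
        f"{int(round(interval_us))}" if math.isclose(interval_us, round(interval_us)) else f"{interval_us!r}"
    )
    hdr = io.StringIO()
    hdr.write("Brain Vision Data Exchange Header File Version 1.0\n")
    hdr.write("[Common Infos]\nCodepage=UTF-8\n")
    hdr.write(f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n")
    hdr.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
    hdr.write(f"NumberOfChannels={rec.n_channels}\n")
    hdr.write(f"SamplingInterval={interval_str}\n")
    hdr.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
    hdr.write("[Channel Infos]\n")
    for i, name in enumerate(rec.channel_labels):
        hdr.write(f"Ch{i + 1}={name},,1,µV\n")
    vhdr.write_text(hdr.getvalue(), encoding="utf-8")

    mrk = io.StringIO()
    mrk.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
    mrk.write("[Common Infos]\nCodepage=UTF-8\n")
    mrk.write(f"DataFile={eeg.name}\n")
    mrk.write("[Marker Infos]\n")
    mrk.write("Mk1=New Segment,,1,1,0,20000101000000000000\n")
    for i, ev in enumerate(rec.events):
        key = (ev.kind, ev.condition, ev.direction)
        desc = inv.get(key, f"{ev.kind.value}|{ev.condition.value}|{ev.direction.value}")
        mrk.write(f"Mk{i + 2}=Stimulus,{desc},{ev.sample_index + 1},1,0\n")
    vmrk.write_text(mrk.getvalue(), encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def canonical_code_map(events: list[Event]) -> dict:
    """Code map matching the canonical descriptions emitted by the writer."""
    out = {}
    for ev in events:
        desc = f"{ev.kind.value}|{ev.condition.value}|{ev.direction.value}"
        out[desc] = (ev.kind, ev.condition, ev.direction)
    return out


# ---------------------------------------------------------------------------
# Behavioral tables


@dataclass
class TrialBehavior:
    """Per-trial behavioral record derived from button-press events.

    Times are seconds in trial time; ``vection_intervals`` are ordered,
    non-overlapping (onset, offset) pairs; ``strength`` is the verbal 0-10
    rating collected at the end of the trial.
    """

    trial: int
    condition: Condition
    direction: Direction
    motion_onset_time: float
    motion_offset_time: float
    vection_intervals: list[tuple[float, float]] = field(default_factory=list)
    strength: int = 0

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        self.direction = Direction(self.direction)
        if not (0 <= int(self.strength) <= 10) or int(self.strength) != self.strength:
            raise ValidationError(f"strength {self.strength!r} outside integer 0-10 scale")
        self.strength = int(self.strength)
        prev_end = None
        for onset, offset in self.vection_intervals:
            if offset < onset:
                raise ValidationError("vection interval with offset before onset")
            if prev_end is not None and onset < prev_end:
                raise ValidationError("overlapping vection intervals")
            prev_end = offset


_BEHAVIOR_COLUMNS = [
    "trial",
    "condition",
    "direction",
    "motion_onset_s",
    "motion_offset_s",
    "vection_onsets_s",
    "vection_offsets_s",
    "strength",
]


def write_behavior_table(rows: list[TrialBehavior], path: str | Path) -> Path:
    """Write trials as UTF-8 CSV; interval lists are ';'-joined float columns."""
    path = Path(path)
    recs = []
    for r in rows:
        recs.append(
            {
                "trial": r.trial,
                "condition": r.condition.value,
                "direction": r.direction.value,
                "motion_onset_s": r.motion_onset_time,
                "motion_offset_s": r.motion_offset_time,
                "vection_onsets_s": ";".join(repr(a) for a, _ in r.vection_intervals),
                "vection_offsets_s": ";".join(repr(b) for _, b in r.vection_intervals),
                "strength": r.strength,
            }
        )
    pd.DataFrame(recs, columns=_BEHAVIOR_COLUMNS).to_csv(path, index=False)
    return path


def read_behavior_table(path: str | Path) -> list[TrialBehavior]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in _BEHAVIOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"behavior table missing columns: {missing}")
    rows: list[TrialBehavior] = []
    for _, r in df.iterrows():
        try:
            cond = Condition(str(r["condition"]))
            direc = Direction(str(r["direction"]))
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
        strength = float(r["strength"])
        if not (0 <= strength <= 10) or strength != int(strength):
            raise ValidationError(f"strength {r['strength']!r} outside integer 0-10 scale")
        onsets = [float(x) for x in str(r["vection_onsets_s"]).split(";") if x]
        offsets = [float(x) for x in str(r["vection_offsets_s"]).split(";") if x]
        if len(onsets) != len(offsets):
            raise ValidationError("unbalanced vection onset/offset columns")
        rows.append(
            TrialBehavior(
                trial=int(r["trial"]),
                condition=cond,
                direction=direc,
                motion_onset_time=float(r["motion_onset_s"]),
                motion_offset_time=float(r["motion_offset_s"]),
                vection_intervals=list(zip(onsets, offsets)),
                strength=int(strength),
            )
        )
    return rows


def write_results_table(rows: list[dict] | pd.DataFrame, path: str | Path) -> Path:
    """Write an analysis results table as UTF-8 CSV with a header row."""
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return path
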
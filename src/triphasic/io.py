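"""Session data model and plain-text bundle I/O.

A recording session is one probe's worth of sorted units (single and
multi-units pooled as "active units"), their spike trains, and the
stimulus event table.  On disk a session is a directory of three
delimited tables plus a JSON metadata sidecar::

    units.tsv    unit_id  area  channel  depth_um  normalized_depth  unit_type
    spikes.tsv   unit_id  time_s
    events.tsv   time_s  kind  duration_ms  intensity_mw  hand_on_bar  lag_ms
    metadata.json

Times are stored in seconds with microsecond precision, which makes the
round-trip lossless for trains produced by the synthetic generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG

AREAS = ("S1", "M1")
UNIT_TYPES = ("single", "multi")
EVENT_KINDS = ("hand", "cortical", "hand_plus_cortical", "sham",
               "hand_off_bar", "paired_pulse_second")


class BundleFormatError(ValueError):
    """Raised when a session bundle fails schema validation."""


@dataclass
class Unit:
    """One sorted unit: identity, position on the probe, spike train."""

    unit_id: str
    area: str
    channel: int
    spike_times: np.ndarray
    depth_um: float = float("nan")
    normalized_depth: float = float("nan")
    unit_type: str = "multi"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.area not in AREAS:
            raise BundleFormatError(f"unknown area {self.area!r}")
        if self.unit_type not in UNIT_TYPES:
            raise BundleFormatError(f"unknown unit_type {self.unit_type!r}")
        if np.any(np.diff(self.spike_times) <= 0):
            raise BundleFormatError(
                f"unit {self.unit_id}: spike times must be strictly increasing")
        if not np.isnan(self.normalized_depth) and not (
                0.0 <= self.normalized_depth <= 1.0):
            raise BundleFormatError(
                f"unit {self.unit_id}: normalized_depth outside [0, 1]")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Unit):
            return NotImplemented
        same_meta = (
            self.unit_id == other.unit_id and self.area == other.area
            and self.channel == other.channel
            and self.unit_type == other.unit_type
            and _nan_eq(self.depth_um, other.depth_um)
            and _nan_eq(self.normalized_depth, other.normalized_depth))
        return same_meta and np.array_equal(self.spike_times, other.spike_times)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus event; times s, duration ms, intensity mW."""

    time: float
    kind: str
    duration_ms: float = 5.0
    intensity_mw: float = 5.0
    hand_on_bar: bool = True
    lag_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise BundleFormatError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise BundleFormatError("event time must be non-negative")
        if self.kind != "sham" and self.duration_ms <= 0:
            raise BundleFormatError("non-sham events need a positive duration")


@dataclass
class RecordingSession:
    """One probe recording: units, events, and session metadata."""

    session_id: str
    animal_id: str
    area: str
    units: List[Unit]
    events: List[StimulusEvent]
    probe_coordinates_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.units:
            raise BundleFormatError("a session needs at least one unit")
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise BundleFormatError("events must be sorted by time")

    def events_of_kind(self, *kinds: str) -> List[StimulusEvent]:
        return [e for e in self.events if e.kind in kinds]

    def event_times(self, *kinds: str) -> np.ndarray:
        evs = self.events_of_kind(*kinds) if kinds else self.events
        return np.array([e.time for e in evs], dtype=float)

    def unit_map(self) -> Dict[str, Unit]:
        return {u.unit_id: u for u in self.units}


@dataclass
class Cohort:
    """Paired S1 + M1 sessions sharing recording/animal identifiers."""

    pairs: List[Tuple[RecordingSession, RecordingSession]]

    def __post_init__(self) -> None:
        ids = [s1.session_id for s1, _ in self.pairs]
        if len(set(ids)) != len(ids):
            raise BundleFormatError("pairing keys must be unique")
        for s1, m1 in self.pairs:
            if (s1.area, m1.area) != ("S1", "M1"):
                raise BundleFormatError("each pair must be (S1, M1)")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _nan_eq(a: float, b: float) -> bool:
    return (np.isnan(a) and np.isnan(b)) or a == b


# ---------------------------------------------------------------------------
# bundle writer / reader


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6f}"


def write_session_bundle(session: RecordingSession, path) -> Path:
    """Write ``session`` as a TSV bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "units.tsv", "w") as fh:
        fh.write("unit_id\tarea\tchannel\tdepth_um\tnormalized_depth\tunit_type\n")
        for u in session.units:
            fh.write(f"{u.unit_id}\t{u.area}\t{u.channel}\t{_fmt(u.depth_um)}"
                     f"\t{_fmt(u.normalized_depth)}\t{u.unit_type}\n")
    with open(path / "spikes.tsv", "w") as fh:
        fh.write("unit_id\ttime_s\n")
        for u in session.units:
            for t in u.spike_times:
                fh.write(f"{u.unit_id}\t{t:.6f}\n")
    with open(path / "events.tsv", "w") as fh:
        fh.write("time_s\tkind\tduration_ms\tintensity_mw\thand_on_bar\tlag_ms\n")
        for e in session.events:
            lag = "" if e.lag_ms is None else f"{e.lag_ms:.6f}"
            fh.write(f"{e.time:.6f}\t{e.kind}\t{e.duration_ms:.6f}"
                     f"\t{e.intensity_mw:.6f}\t{int(e.hand_on_bar)}\t{lag}\n")
    meta = {
        "session_id": session.session_id,
        "animal_id": session.animal_id,
        "area": session.area,
        "probe_coordinates_mm": list(session.probe_coordinates_mm),
        "notes": session.notes,
    }
    with open(path / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


_REQUIRED = {
    "units.tsv": ["unit_id", "area", "channel", "depth_um",
                  "normalized_depth", "unit_type"],
    "spikes.tsv": ["unit_id", "time_s"],
    "events.tsv": ["time_s", "kind", "duration_ms", "intensity_mw",
                   "hand_on_bar", "lag_ms"],
}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    fp = path / name
    if not fp.exists():
        raise BundleFormatError(f"missing table {name}")
    df = pd.read_csv(fp, sep="\t", dtype={"unit_id": str})
    missing = [c for c in _REQUIRED[name] if c not in df.columns]
    if missing:
        raise BundleFormatError(f"{name}: missing required columns {missing}")
    return df


def read_session_bundle(path) -> RecordingSession:
    """Read a TSV bundle directory back into a :class:`RecordingSession`."""
    path = Path(path)
    units_df = _read_table(path, "units.tsv")
    spikes_df = _read_table(path, "spikes.tsv")
    events_df = _read_table(path, "events.tsv")
    meta_fp = path / "metadata.json"
    if not meta_fp.exists():
        raise BundleFormatError("missing metadata.json")
    meta = json.loads(meta_fp.read_text())

    spikes_by_unit = {
        uid: np.asarray(grp["time_s"], dtype=float)
        for uid, grp in spikes_df.groupby("unit_id", sort=False)
    }
    units = []
    for row in units_df.itertuples(index=False):
        units.append(Unit(
            unit_id=row.unit_id,
            area=row.area,
            channel=int(row.channel),
            spike_times=spikes_by_unit.get(row.unit_id, np.empty(0)),
            depth_um=float(row.depth_um) if pd.notna(row.depth_um) else float("nan"),
            normalized_depth=(float(row.normalized_depth)
                              if pd.notna(row.normalized_depth) else float("nan")),
            unit_type=row.unit_type,
        ))
    events = []
    for row in events_df.itertuples(index=False):
        events.append(StimulusEvent(
            time=float(row.time_s),
            kind=row.kind,
            duration_ms=float(row.duration_ms),
            intensity_mw=float(row.intensity_mw),
            hand_on_bar=bool(int(row.hand_on_bar)),
            lag_ms=float(row.lag_ms) if pd.notna(row.lag_ms) else None,
        ))
    return RecordingSession(
        session_id=meta["session_id"],
        animal_id=meta["animal_id"],
        area=meta["area"],
        units=units,
        events=events,
        probe_coordinates_mm=tuple(meta.get("probe_coordinates_mm", (0, 0, 0))),
        notes=meta.get("notes", ""),
    )


# ---------------------------------------------------------------------------
# validation and inclusion filters


def validate_session(session: RecordingSession,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> List[str]:
    """Report-only consistency checks; returns a list of violations."""
    report: List[str] = []
    for u in session.units:
        if np.any(np.diff(u.spike_times) <= 0):
            report.append(f"unit {u.unit_id}: non-monotone spike times")
        if not np.isnan(u.normalized_depth) and not (
                0.0 <= u.normalized_depth <= 1.0):
            report.append(f"unit {u.unit_id}: normalized_depth out of range")
    times = session.event_times()
    span_s = (config.span_ms[1] - config.span_ms[0]) / 2000.0
    gaps = np.diff(times)
    for i, g in enumerate(gaps):
        if g < span_s:
            report.append(
                f"events {i} and {i + 1} are {g:.3f} s apart, closer than "
                f"the {span_s:.3f} s half-span; alignment windows overlap")
    if np.any(times < 0):
        report.append("negative event time")
    return report


def select_active_units(session: RecordingSession,
                        min_units: int = 15) -> Optional[RecordingSession]:
    """Inclusion filter: keep the session iff it has >= ``min_units``.

    Single and multi-units are pooled as active units; the per-unit
    ``unit_type`` labels are preserved for stratified summaries.
    Returns the session unchanged when accepted, ``None`` otherwise.
    """
    if len(session.units) >= min_units:
        return session
    return None
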
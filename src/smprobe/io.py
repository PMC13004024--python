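"""Containers and on-disk formats for multichannel single-molecule traces.

One directory holds one experiment: per-frame intensities for every molecule
in a single wide TSV (``traces.tsv``, one column per molecule x channel) and
the experiment metadata in a JSON sidecar (``metadata.json``) carrying a
``schema_version`` field.  Binding events travel in a plain TSV with one row
per event.

Conventions
-----------
* Frame index is 0-based; frame ``f`` covers the half-open time interval
  ``[f * dt, (f + 1) * dt)`` with ``dt`` the frame period in seconds.
* All event times are in seconds and intervals are half-open ``[start, end)``.
* Channel names are ``donor``, ``transcription`` and ``acceptor_1`` ..
  ``acceptor_3``; the metadata maps each acceptor channel to the reporter
  (DNA probe or protein) it detects.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"
TRACES_FILENAME = "traces.tsv"
META_FILENAME = "metadata.json"

DONOR = "donor"
TRANSCRIPTION = "transcription"
ACCEPTOR_PREFIX = "acceptor_"

#: canonical column order of an event table (times in seconds)
EVENT_COLUMNS = (
    "molecule_id",
    "reporter",
    "t_start",
    "t_end",
    "left_censored",
    "right_censored",
)


class FormatError(ValueError):
    """Raised when an on-disk experiment or event file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when an in-memory container violates its invariants."""


def is_acceptor(channel: str) -> bool:
    return channel.startswith(ACCEPTOR_PREFIX)


@dataclass(frozen=True)
class ExperimentMeta:
    """Per-experiment metadata shared by all molecules.

    Parameters
    ----------
    frame_period
        Camera integration time per frame, seconds.
    channel_reporter_map
        Maps each acceptor channel (``acceptor_1`` ...) to the reporter it
        detects, e.g. ``{"acceptor_1": "H30"}``.
    probe_concentrations
        Reporter -> concentration in molar of the labeled species in solution.
    delivery_time
        Time (s) at which the reaction mix (probes, protein, NTPs) becomes
        active; binding and transcription elongation are measured from here.
    dead_time
        ``(start, length)`` in seconds of the laser-off window used for
        reagent injection; frames inside it carry no signal.
    """

    frame_period: float = 0.1
    channel_reporter_map: dict[str, str] = field(default_factory=dict)
    probe_concentrations: dict[str, float] = field(default_factory=dict)
    delivery_time: float = 25.0
    dead_time: tuple[float, float] = (15.0, 10.0)
    channels: tuple[str, ...] | None = None  # channel order of the crosstalk matrix
    crosstalk: tuple[tuple[float, ...], ...] | None = None  # calibrated leakage
    schema_version: str = SCHEMA_VERSION

    @property
    def dead_window(self) -> tuple[float, float]:
        """Dead time as an absolute half-open interval ``[start, end)``."""
        start, length = self.dead_time
        return (start, start + length)

    def reporter_channel(self, reporter: str) -> str:
        for channel, rep in self.channel_reporter_map.items():
            if rep == reporter:
                return channel
        raise KeyError(f"no channel mapped to reporter {reporter!r}")

    @property
    def reporters(self) -> list[str]:
        return [self.channel_reporter_map[c] for c in sorted(self.channel_reporter_map)]


@dataclass
class Trace:
    """Per-frame intensities (arbitrary units) of one molecule."""

    molecule_id: str
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    def validate(self) -> None:
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValidationError(
                f"molecule {self.molecule_id!r}: channel lengths differ: {lengths}"
            )

    def acceptor_channels(self) -> list[str]:
        return sorted(c for c in self.channels if is_acceptor(c))


@dataclass
class TraceSet:
    """A set of molecules acquired under one experimental condition."""

    traces: list[Trace]
    meta: ExperimentMeta

    @property
    def n_molecules(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def trace(self, molecule_id: str) -> Trace:
        for t in self.traces:
            if t.molecule_id == molecule_id:
                return t
        raise KeyError(molecule_id)

    def validate(self) -> None:
        if self.meta.frame_period <= 0:
            raise ValidationError("frame_period must be > 0")
        seen: set[str] = set()
        for t in self.traces:
            t.validate()
            if t.molecule_id in seen:
                raise ValidationError(f"duplicate molecule_id {t.molecule_id!r}")
            seen.add(t.molecule_id)
            for c in t.acceptor_channels():
                if c not in self.meta.channel_reporter_map:
                    raise ValidationError(
                        f"acceptor channel {c!r} has no reporter in channel_reporter_map"
                    )

    def duration(self) -> float:
        """Total acquisition time (s) of the longest trace."""
        n = max((t.n_frames for t in self.traces), default=0)
        return n * self.meta.frame_period


# ---------------------------------------------------------------------------
# trace directory round trip
# ---------------------------------------------------------------------------


def _column_name(molecule_id: str, channel: str) -> str:
    return f"{molecule_id}|{channel}"


def write_traces(traces: TraceSet, path: str | os.PathLike) -> None:
    """Write an experiment directory (wide TSV + JSON sidecar).

    The round trip ``read_traces(write_traces(x))`` restores intensities and
    metadata bit-exactly (floats are serialized with shortest round-trip
    repr).
    """
    traces.validate()
    os.makedirs(path, exist_ok=True)
    n_max = max((t.n_frames for t in traces.traces), default=0)
    data: dict[str, np.ndarray] = {
        "time_s": np.arange(n_max) * traces.meta.frame_period
    }
    molecules_meta = []
    for t in traces.traces:
        molecules_meta.append(
            {"id": t.molecule_id, "n_frames": t.n_frames, "channels": sorted(t.channels)}
        )
        for ch in sorted(t.channels):
            col = np.full(n_max, np.nan)
            col[: t.n_frames] = t.channels[ch]
            data[_column_name(t.molecule_id, ch)] = col
    # shortest round-trip repr keeps the TSV bit-exact for float64
    pd.DataFrame(data).to_csv(
        os.path.join(path, TRACES_FILENAME),
        sep="\t",
        index=False,
        float_format=lambda v: repr(float(v)),
    )
    meta = {
        "schema_version": traces.meta.schema_version,
        "frame_period": traces.meta.frame_period,
        "channel_reporter_map": traces.meta.channel_reporter_map,
        "probe_concentrations": traces.meta.probe_concentrations,
        "delivery_time": traces.meta.delivery_time,
        "dead_time": list(traces.meta.dead_time),
        "channels": list(traces.meta.channels) if traces.meta.channels else None,
        "crosstalk": (
            [list(row) for row in traces.meta.crosstalk]
            if traces.meta.crosstalk is not None
            else None
        ),
        "molecules": molecules_meta,
    }
    with open(os.path.join(path, META_FILENAME), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_traces(path: str | os.PathLike) -> TraceSet:
    """Read an experiment directory written by :func:`write_traces`."""
    meta_path = os.path.join(path, META_FILENAME)
    if not os.path.exists(meta_path):
        raise FormatError(f"missing metadata sidecar {META_FILENAME} in {path}")
    with open(meta_path) as fh:
        raw = json.load(fh)
    if raw.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(f"unknown schema version {raw.get('schema_version')!r}")
    meta = ExperimentMeta(
        frame_period=float(raw["frame_period"]),
        channel_reporter_map=dict(raw["channel_reporter_map"]),
        probe_concentrations={k: float(v) for k, v in raw["probe_concentrations"].items()},
        delivery_time=float(raw["delivery_time"]),
        dead_time=tuple(float(v) for v in raw["dead_time"]),
        channels=tuple(raw["channels"]) if raw.get("channels") else None,
        crosstalk=(
            tuple(tuple(float(v) for v in row) for row in raw["crosstalk"])
            if raw.get("crosstalk")
            else None
        ),
    )
    df = pd.read_csv(
        os.path.join(path, TRACES_FILENAME), sep="\t", float_precision="round_trip"
    )
    traces = []
    for mol in raw["molecules"]:
        n = int(mol["n_frames"])
        channels = {}
        for ch in mol["channels"]:
            col = _column_name(mol["id"], ch)
            if col not in df.columns:
                raise FormatError(f"missing column {col!r} in {TRACES_FILENAME}")
            values = df[col].to_numpy(dtype=float)
            tail = values[n:]
            if np.isfinite(values[:n]).sum() != n or np.isfinite(tail).any():
                raise FormatError(
                    f"column {col!r} length inconsistent with metadata n_frames={n}"
                )
            channels[ch] = values[:n]
        traces.append(Trace(molecule_id=str(mol["id"]), channels=channels))
    ts = TraceSet(traces=traces, meta=meta)
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------


@dataclass
class EventTable:
    """Binding events, one row per event per molecule per reporter.

    Columns: ``molecule_id, reporter, t_start, t_end`` (seconds, half-open)
    and boolean ``left_censored`` / ``right_censored`` flags set where the
    observed interval is truncated by the trace start/end, the dead-time
    window, or donor photobleaching.
    """

    df: pd.DataFrame

    @staticmethod
    def empty() -> "EventTable":
        return EventTable(
            pd.DataFrame(
                {
                    "molecule_id": pd.Series(dtype=str),
                    "reporter": pd.Series(dtype=str),
                    "t_start": pd.Series(dtype=float),
                    "t_end": pd.Series(dtype=float),
                    "left_censored": pd.Series(dtype=bool),
                    "right_censored": pd.Series(dtype=bool),
                }
            )
        )

    @staticmethod
    def from_records(rows: list[dict]) -> "EventTable":
        if not rows:
            return EventTable.empty()
        df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
        return EventTable(df).canonical()

    def canonical(self) -> "EventTable":
        """Rows sorted by (molecule, reporter, start), index reset."""
        columns = list(EVENT_COLUMNS)
        if "duration" in self.df.columns:
            columns.append("duration")
            self.df["duration"] = self.df["duration"].fillna(
                self.df["t_end"] - self.df["t_start"]
            )
        if "t_start_sub" in self.df.columns:
            columns.append("t_start_sub")
            self.df["t_start_sub"] = self.df["t_start_sub"].fillna(self.df["t_start"])
        df = self.df[columns].sort_values(
            ["molecule_id", "reporter", "t_start", "t_end"], kind="mergesort"
        )
        df = df.reset_index(drop=True)
        df["left_censored"] = df["left_censored"].astype(bool)
        df["right_censored"] = df["right_censored"].astype(bool)
        return EventTable(df)

    def validate(self) -> None:
        df = self.df
        if (df["t_end"] <= df["t_start"]).any():
            bad = df[df["t_end"] <= df["t_start"]].iloc[0]
            raise ValidationError(
                f"event with t_end <= t_start for molecule {bad['molecule_id']!r}"
            )
        for (mid, rep), grp in df.groupby(["molecule_id", "reporter"], sort=False):
            starts = grp["t_start"].to_numpy()
            ends = grp["t_end"].to_numpy()
            order = np.argsort(starts, kind="mergesort")
            if (starts[order][1:] < ends[order][:-1]).any():
                raise ValidationError(
                    f"overlapping events for molecule {mid!r}, reporter {rep!r}"
                )

    # -- convenience accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    def select(self, molecule_id: str | None = None, reporter: str | None = None) -> "EventTable":
        df = self.df
        if molecule_id is not None:
            df = df[df["molecule_id"] == molecule_id]
        if reporter is not None:
            df = df[df["reporter"] == reporter]
        return EventTable(df.reset_index(drop=True))

    @property
    def durations(self) -> np.ndarray:
        """Event durations (s); the sub-frame ``duration`` column when present."""
        if "duration" in self.df.columns:
            return self.df["duration"].to_numpy()
        return (self.df["t_end"] - self.df["t_start"]).to_numpy()

    @property
    def censored(self) -> np.ndarray:
        return (self.df["left_censored"] | self.df["right_censored"]).to_numpy()

    def total_time_in(self, start: float, end: float) -> float:
        """Summed overlap (s) of all events with the window ``[start, end)``."""
        lo = np.maximum(self.df["t_start"].to_numpy(), start)
        hi = np.minimum(self.df["t_end"].to_numpy(), end)
        return float(np.clip(hi - lo, 0.0, None).sum())

    def equals(self, other: "EventTable") -> bool:
        a, b = self.canonical().df, other.canonical().df
        if len(a) == 0 and len(b) == 0:
            return list(a.columns) == list(b.columns)
        return a.equals(b)


def write_events(events: EventTable, path: str | os.PathLike) -> None:
    """Write an event table as TSV (header mandatory, times in seconds).

    Only the canonical columns are serialized; the in-memory sub-frame
    ``duration`` column, when present, is a derived quantity and is dropped.
    """
    df = events.canonical().df[list(EVENT_COLUMNS)].rename(
        columns={"t_start": "t_start_s", "t_end": "t_end_s"}
    )
    df["left_censored"] = df["left_censored"].astype(int)
    df["right_censored"] = df["right_censored"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format=lambda v: repr(float(v)))


def read_events(path: str | os.PathLike) -> EventTable:
    """Read and validate an event TSV written by :func:`write_events`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"molecule_id": str, "reporter": str},
        float_precision="round_trip",
    )
    expected = {"molecule_id", "reporter", "t_start_s", "t_end_s", "left_censored", "right_censored"}
    if not expected.issubset(df.columns):
        raise FormatError(f"event file {path} missing columns {expected - set(df.columns)}")
    df = df.rename(columns={"t_start_s": "t_start", "t_end_s": "t_end"})
    df["molecule_id"] = df["molecule_id"].astype(str)
    df["reporter"] = df["reporter"].astype(str)
    df["t_start"] = df["t_start"].astype(float)
    df["t_end"] = df["t_end"].astype(float)
    df["left_censored"] = df["left_censored"].astype(bool)
    df["right_censored"] = df["right_censored"].astype(bool)
    table = EventTable(df).canonical()
    table.validate()
    return table


__all__ = [
    "DONOR",
    "TRANSCRIPTION",
    "EVENT_COLUMNS",
    "EventTable",
    "ExperimentMeta",
    "FormatError",
    "SCHEMA_VERSION",
    "Trace",
    "TraceSet",
    "ValidationError",
    "is_acceptor",
    "read_events",
    "read_traces",
    "write_events",
    "write_traces",
]
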
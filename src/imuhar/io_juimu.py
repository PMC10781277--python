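"""Reading and writing the JU-IMU CSV dialect and segment annotations.

A recording is one participant-task session: a CSV whose first column is a
timestamp in seconds and whose remaining 45 columns are the raw sensor
channels in :mod:`imuhar.layout` order.  Segment annotations live in a
separate CSV table (one per task) with explicit sample-index boundaries;
segments use 0-based, half-open ``[start, end)`` indices.

The loader applies the study's exclusion rule: a participant whose task data
misses more than one movement segment is dropped entirely (a single missing
segment is tolerated), and every exclusion is logged with its reason.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .layout import RAW_LAYOUT, Channel, ChannelLayout

GROUPS = ("ND", "Stroke")
SIDES = ("none", "left", "right")
TASKS = ("ROM", "ADL")
MOVEMENT_TYPES = ("UNI", "BIA", "BIS")

ANNOTATION_COLUMNS = [
    "participant_id",
    "group",
    "hemiparesis_side",
    "task",
    "movement_id",
    "movement_type",
    "start_index",
    "end_index",
]


@dataclass
class Recording:
    """One participant-task multichannel time series."""

    participant_id: str
    group: str
    hemiparesis_side: str
    task: str
    timestamps: np.ndarray  # (T,) seconds, nondecreasing
    values: np.ndarray  # (T, 45)
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values row counts differ")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.hemiparesis_side not in SIDES:
            raise ValueError(f"unknown side {self.hemiparesis_side!r}")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class SegmentAnnotation:
    """Label and sample-index boundaries of one movement segment."""

    participant_id: str
    task: str
    movement_id: int
    movement_type: str
    start_index: int
    end_index: int

    def __post_init__(self) -> None:
        if self.movement_type not in MOVEMENT_TYPES:
            raise ValueError(f"unknown movement type {self.movement_type!r}")
        if not (0 <= self.start_index < self.end_index):
            raise ValueError(
                f"invalid segment bounds [{self.start_index}, {self.end_index})"
            )


@dataclass
class Segment:
    """An annotated slice of a recording, carried with its metadata.

    ``channels`` names each column of ``values``; preprocessing steps that
    select or reorder channels update it, so downstream code never guesses
    the layout.
    """

    participant_id: str
    group: str
    hemiparesis_side: str
    task: str
    movement_id: int
    movement_type: str
    values: np.ndarray  # (length, n_channels)
    channels: list[Channel]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError("values width does not match channel list")

    def __len__(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, channels: list[Channel] | None = None,
                    **provenance) -> "Segment":
        seg = replace(self, values=values,
                      channels=list(channels if channels is not None else self.channels))
        if provenance:
            seg.provenance = {**self.provenance, **provenance}
        return seg


@dataclass
class Dataset:
    """Materialized segments plus a log of excluded participants/annotations."""

    segments: list[Segment]
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.segments:
            seen.setdefault(s.participant_id, None)
        return list(seen)

    def by_participant(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.participant_id, []).append(s)
        return out


# ---------------------------------------------------------------------------
# recordings


def read_recording(
    path: str | os.PathLike,
    *,
    participant_id: str,
    group: str,
    hemiparesis_side: str = "none",
    task: str,
    layout: ChannelLayout = RAW_LAYOUT,
    header_map: Mapping[str, str] | None = None,
) -> Recording:
    """Read one recording CSV.

    The header must be ``timestamp`` followed by the 45 layout column names,
    or translate to them through ``header_map`` (on-disk name -> layout
    name).  Rows containing non-numeric cells are dropped and counted in
    ``Recording.n_dropped_rows``.
    """
    df = pd.read_csv(path, dtype=str)
    if header_map:
        df = df.rename(columns=dict(header_map))
    expected = ["timestamp"] + layout.column_names()
    if list(df.columns) != expected:
        raise ValueError(
            f"malformed header in {path}: expected {len(expected)} layout "
            f"columns, got {list(df.columns)[:4]}..."
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    good = ~numeric.isna().any(axis=1)
    n_dropped = int((~good).sum())
    numeric = numeric[good]
    return Recording(
        participant_id=participant_id,
        group=group,
        hemiparesis_side=hemiparesis_side,
        task=task,
        timestamps=numeric["timestamp"].to_numpy(),
        values=numeric[layout.column_names()].to_numpy(),
        n_dropped_rows=n_dropped,
    )


def write_recording(
    path: str | os.PathLike, recording: Recording, layout: ChannelLayout = RAW_LAYOUT
) -> None:
    """Write a recording in the CSV dialect (values at 8 significant digits)."""
    df = pd.DataFrame(recording.values, columns=layout.column_names())
    df.insert(0, "timestamp", recording.timestamps)
    df.to_csv(path, index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(
    path: str | os.PathLike, column_map: Mapping[str, str] | None = None
) -> tuple[list[SegmentAnnotation], pd.DataFrame]:
    """Read an annotation table.

    ``column_map`` translates on-disk column names to the canonical ones (the
    released data's exact schema varies, so the mapping is declared by the
    caller).  Returns the annotations plus the raw table, which carries the
    per-participant group/side metadata used to pair annotations with
    recordings.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    anns = [
        SegmentAnnotation(
            participant_id=str(r.participant_id),
            task=str(r.task),
            movement_id=int(r.movement_id),
            movement_type=str(r.movement_type),
            start_index=int(r.start_index),
            end_index=int(r.end_index),
        )
        for r in df.itertuples()
    ]
    return anns, df


def write_annotations(path: str | os.PathLike, rows: pd.DataFrame) -> None:
    rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset assembly


def load_dataset(
    recordings: Sequence[Recording],
    annotations: Sequence[SegmentAnnotation],
    task: str,
    expected_movements: Iterable[int] | None = None,
    max_missing: int = 1,
) -> Dataset:
    """Slice annotated segments out of recordings and apply exclusion rules.

    A participant is retained only if at most ``max_missing`` of the task's
    expected movements are absent (unannotated or out of recording bounds).
    ``expected_movements`` defaults to every movement id annotated for the
    task across all participants — with complete data this equals the task's
    movement set.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    recs = {r.participant_id: r for r in recordings if r.task == task}
    task_anns = [a for a in annotations if a.task == task]
    if expected_movements is None:
        expected_movements = {a.movement_id for a in task_anns}
    expected = set(expected_movements)

    exclusion_log: list[tuple[str, str]] = []
    per_participant: dict[str, list[Segment]] = {}
    for ann in task_anns:
        rec = recs.get(ann.participant_id)
        if rec is None:
            exclusion_log.append(
                (ann.participant_id, f"movement {ann.movement_id}: no recording")
            )
            continue
        if ann.end_index > len(rec):
            exclusion_log.append(
                (
                    ann.participant_id,
                    f"movement {ann.movement_id}: annotation "
                    f"[{ann.start_index}, {ann.end_index}) exceeds recording "
                    f"length {len(rec)}",
                )
            )
            continue
        seg = Segment(
            participant_id=rec.participant_id,
            group=rec.group,
            hemiparesis_side=rec.hemiparesis_side,
            task=task,
            movement_id=ann.movement_id,
            movement_type=ann.movement_type,
            values=rec.values[ann.start_index : ann.end_index].copy(),
            channels=RAW_LAYOUT.channels(),
        )
        per_participant.setdefault(rec.participant_id, []).append(seg)

    segments: list[Segment] = []
    for pid in sorted(per_participant, key=_participant_sort_key):
        segs = per_participant[pid]
        have = {s.movement_id for s in segs}
        n_missing = len(expected - have)
        if n_missing > max_missing:
            exclusion_log.append(
                (pid, f"excluded: missing {n_missing} of {len(expected)} segments")
            )
            continue
        segments.extend(segs)
    return Dataset(segments=segments, exclusion_log=exclusion_log)


def _participant_sort_key(pid: str) -> tuple:
    """Natural ordering so Stroke2 sorts before Stroke10."""
    head = pid.rstrip("0123456789")
    tail = pid[len(head):]
    return (head, int(tail) if tail else -1)
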
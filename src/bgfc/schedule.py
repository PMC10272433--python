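"""Alertness-motor paradigm schedule and task segmentation.

The paradigm interleaves three tasks — sensorimotor (T1), intrinsic
alertness (T2) and extrinsic alertness (T3) — in pseudorandomised order,
each repeated in four blocks. Cleaned full-length series are split by the
block timings of one task and the four blocks are concatenated to form that
task's segment; single blocks feed the block-1 vs block-4 fatigue
contrasts.

Volume membership uses half-open floor-indexed windows on 0-based
indices: ``[floor((onset+lag)/TR), floor((onset+lag+duration)/TR))``.
For TR-aligned onsets (the default schedule) this is exactly the set of
volumes whose acquisition start falls inside the (optionally
haemodynamic-lag shifted) block window; a block shorter than one TR
resolves to an empty range and is an error. No lag is imposed by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "BlockEntry",
    "ParadigmSchedule",
    "TaskSegmentSeries",
    "default_schedule",
    "volumes_for_block",
    "segment_by_task",
    "segment_single_block",
]

TASKS = ("T1", "T2", "T3")

# tolerance for float onset/TR arithmetic when flooring to volume indices
_EPS = 1e-9


@dataclass(frozen=True)
class BlockEntry:
    task: str
    block: int
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class ParadigmSchedule:
    """Ordered task blocks with onsets and durations (seconds)."""

    entries: tuple[BlockEntry, ...]
    condition: str = "handgrip_only"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        prev_end = -np.inf
        for e in self.entries:
            if e.task not in TASKS:
                raise ValueError(f"unknown task {e.task!r}")
            if e.duration_s <= 0:
                raise ValueError(f"non-positive duration for {e.task} block {e.block}")
            if e.onset_s < prev_end - _EPS:
                raise ValueError("schedule entries overlap or are unsorted")
            prev_end = e.onset_s + e.duration_s
        for task in self.tasks:
            blocks = sorted(e.block for e in self.entries if e.task == task)
            if blocks != [1, 2, 3, 4]:
                raise ValueError(f"task {task} must have blocks 1..4, got {blocks}")

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(t for t in TASKS if any(e.task == t for e in self.entries))

    def blocks_of(self, task: str) -> list[BlockEntry]:
        out = [e for e in self.entries if e.task == task]
        if not out:
            raise KeyError(f"task {task!r} not present in schedule")
        return out

    def entry(self, task: str, block: int) -> BlockEntry:
        for e in self.blocks_of(task):
            if e.block == block:
                return e
        raise KeyError(f"block {block} of task {task} not in schedule")

    @property
    def total_duration_s(self) -> float:
        last = self.entries[-1]
        return last.onset_s + last.duration_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.task, e.block, e.onset_s, e.duration_s) for e in self.entries],
            columns=["task", "block", "onset_s", "duration_s"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition: str = "handgrip_only") -> "ParadigmSchedule":
        entries = tuple(
            BlockEntry(str(r.task), int(r.block), float(r.onset_s), float(r.duration_s))
            for r in frame.itertuples()
        )
        return cls(entries, condition)

    @classmethod
    def from_tsv(cls, path: str | Path, condition: str = "handgrip_only") -> "ParadigmSchedule":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class TaskSegmentSeries:
    """Concatenated within-task samples (T' x regions) with block joins."""

    task: str
    data: np.ndarray
    block_boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        bounds = tuple(self.block_boundaries)
        object.__setattr__(self, "block_boundaries", bounds)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("block boundaries must be strictly increasing")
        if bounds and bounds[-1] >= len(self.data):
            raise ValueError("block boundary beyond segment length")


#: Default block order; pseudorandomised but fixed per schedule, each task 4x.
DEFAULT_ORDER = ("T1", "T2", "T3", "T3", "T1", "T2", "T2", "T3", "T1", "T1", "T3", "T2")


def default_schedule(
    tr_seconds: float = 0.906,
    block_volumes: int = 80,
    rest_volumes: int = 5,
    initial_rest_volumes: int = 10,
    order: tuple[str, ...] = DEFAULT_ORDER,
    condition: str = "handgrip_only",
) -> ParadigmSchedule:
    """Blocked schedule totalling ~15 min at the default TR of 0.906 s.

    Block durations and inter-block rests are free design parameters; the
    defaults (12 x 80-volume blocks, 5-volume rests, 10-volume lead-in;
    1025 volumes = 15.5 min) are chosen only to fill the scan length.
    """
    entries = []
    counts = {t: 0 for t in TASKS}
    vol = initial_rest_volumes
    for i, task in enumerate(order):
        counts[task] += 1
        entries.append(
            BlockEntry(task, counts[task], vol * tr_seconds, block_volumes * tr_seconds)
        )
        vol += block_volumes + (rest_volumes if i < len(order) - 1 else 0)
    return ParadigmSchedule(tuple(entries), condition)


def n_volumes_for(schedule: ParadigmSchedule, tr_seconds: float) -> int:
    """Number of volumes covering the schedule (incl. trailing partial TR)."""
    return int(np.ceil(schedule.total_duration_s / tr_seconds - _EPS))


def volumes_for_block(
    schedule: ParadigmSchedule,
    task: str,
    block: int,
    tr_seconds: float,
    hrf_lag_seconds: float = 0.0,
) -> tuple[int, int]:
    """Half-open volume index range [start, stop) of one task block.

    A volume belongs to the block iff its acquisition start falls inside
    the lag-shifted window ``[onset + lag, onset + lag + duration)``.
    """
    e = schedule.entry(task, block)
    start = int(np.floor((e.onset_s + hrf_lag_seconds) / tr_seconds + _EPS))
    stop = int(np.floor((e.onset_s + hrf_lag_seconds + e.duration_s) / tr_seconds + _EPS))
    start = max(start, 0)
    if stop <= start:
        raise ValueError(
            f"block {block} of {task} resolves to an empty volume range "
            f"(duration {e.duration_s} s < TR {tr_seconds} s?)"
        )
    return start, stop


def segment_by_task(
    data: np.ndarray,
    schedule: ParadigmSchedule,
    task: str,
    tr_seconds: float,
    hrf_lag_seconds: float = 0.0,
) -> TaskSegmentSeries:
    """Concatenate the four block ranges of ``task`` in schedule order."""
    arr = np.asarray(data)
    parts = []
    boundaries = []
    total = 0
    for e in schedule.blocks_of(task):
        start, stop = volumes_for_block(schedule, task, e.block, tr_seconds, hrf_lag_seconds)
        if stop > arr.shape[0]:
            raise ValueError(
                f"block {e.block} of {task} extends past series end "
                f"({stop} > {arr.shape[0]} volumes)"
            )
        parts.append(arr[start:stop])
        total += stop - start
        boundaries.append(total)
    return TaskSegmentSeries(task, np.concatenate(parts, axis=0), tuple(boundaries[:-1]))


def segment_single_block(
    data: np.ndarray,
    schedule: ParadigmSchedule,
    task: str,
    block: int,
    tr_seconds: float,
    hrf_lag_seconds: float = 0.0,
    min_volumes: int | None = None,
) -> np.ndarray:
    """Rows of one block of one task (for block-1 vs block-4 contrasts)."""
    arr = np.asarray(data)
    start, stop = volumes_for_block(schedule, task, block, tr_seconds, hrf_lag_seconds)
    if stop > arr.shape[0]:
        raise ValueError(
            f"block {block} of {task} extends past series end ({stop} > {arr.shape[0]})"
        )
    if min_volumes is not None and stop - start < min_volumes:
        raise ValueError(
            f"block {block} of {task} has {stop - start} volumes, "
            f"below the per-block FC floor of {min_volumes}"
        )
    return arr[start:stop]
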
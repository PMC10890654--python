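"""Domain types and I/O for loop-course split-time data.

A marathon run on a short loop yields one split time per lap.  The types here
model a fixed course of equal-length laps (the 12 m discrepancy between the
nominal ~1279 m lap and 42,195/33 is absorbed by the equal-lap assumption: all
pacing statistics downstream are ratios of speeds, so they depend only on the
lap *times*), a single runner-day race, and a multi-day cohort.

Distances are metres, times seconds, speeds m/s throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RaceCourse",
    "RaceRecord",
    "Cohort",
    "SplitFormatError",
    "SplitDataError",
    "read_split_table",
    "write_split_table",
    "lap_speeds",
    "race_mean_speed",
    "time_at_distance",
    "segment_mean_speed",
]

#: CSV columns of the one supported long-format dialect (1-based day and lap).
SPLIT_COLUMNS = ("runner_id", "day", "lap", "lap_time_s")


class SplitFormatError(ValueError):
    """The split table does not have the expected columns/structure."""


class SplitDataError(ValueError):
    """A row of the split table carries an invalid value."""


@dataclass(frozen=True)
class RaceCourse:
    """A loop course of ``n_laps`` equal laps totalling ``total_distance`` m."""

    total_distance: float = 42195.0
    n_laps: int = 33

    def __post_init__(self) -> None:
        if not self.total_distance > 0:
            raise ValueError("total_distance must be positive")
        if self.n_laps < 2:
            raise ValueError("n_laps must be at least 2")

    @property
    def lap_distance(self) -> float:
        return self.total_distance / self.n_laps


@dataclass(frozen=True)
class RaceRecord:
    """One runner's one-day race: an ordered sequence of lap times.

    Parameters
    ----------
    runner_id
        Opaque label identifying the runner.
    day
        1-based race day.
    course
        The loop course the race was run on.
    lap_times
        Lap split times in seconds, one per lap, in running order.
    """

    runner_id: str
    day: int
    course: RaceCourse
    lap_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.lap_times, dtype=float)
        object.__setattr__(self, "lap_times", times)
        if self.day < 1:
            raise ValueError("day must be >= 1")
        if times.ndim != 1 or len(times) != self.course.n_laps:
            raise ValueError(
                f"expected {self.course.n_laps} lap times, got {times.shape}"
            )
        if not np.all(np.isfinite(times)) or not np.all(times > 0):
            raise ValueError("lap times must be positive and finite")

    @property
    def total_time(self) -> float:
        """Finish time in seconds."""
        return float(self.lap_times.sum())


@dataclass
class Cohort:
    """A collection of races, at most one per (runner, day)."""

    records: list[RaceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.runner_id, rec.day)
            if key in seen:
                raise ValueError(f"duplicate record for runner/day {key}")
            seen.add(key)

    @property
    def days(self) -> list[int]:
        return sorted({r.day for r in self.records})

    @property
    def runners(self) -> list[str]:
        return sorted({r.runner_id for r in self.records})

    @property
    def complete_runners(self) -> list[str]:
        """Runners present on every day of the cohort."""
        days = set(self.days)
        by_runner: dict[str, set[int]] = {}
        for r in self.records:
            by_runner.setdefault(r.runner_id, set()).add(r.day)
        return sorted(rid for rid, ds in by_runner.items() if ds == days)

    def get(self, runner_id: str, day: int) -> RaceRecord:
        for r in self.records:
            if r.runner_id == runner_id and r.day == day:
                return r
        raise KeyError((runner_id, day))

    def complete(self) -> "Cohort":
        """Sub-cohort restricted to runners who raced on every day."""
        keep = set(self.complete_runners)
        return Cohort([r for r in self.records if r.runner_id in keep])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_split_table(path, course: RaceCourse | None = None) -> Cohort:
    """Read a long-format CSV of lap split times into a :class:`Cohort`.

    The file must have columns ``runner_id, day, lap, lap_time_s`` with lap
    indices 1..n_laps contiguous for each runner-day.  Runner-days with a
    wrong number of laps (e.g. a missed chip read) are excluded with a
    warning; malformed values raise.

    Raises
    ------
    SplitFormatError
        Missing/extra required column.
    SplitDataError
        Non-positive or non-numeric lap time, or duplicate (runner, day, lap).
    """
    course = course or RaceCourse()
    df = pd.read_csv(path, dtype={"runner_id": str})
    missing = set(SPLIT_COLUMNS) - set(df.columns)
    if missing:
        raise SplitFormatError(f"missing required column(s): {sorted(missing)}")
    if df.empty:
        return Cohort([])

    times = pd.to_numeric(df["lap_time_s"], errors="coerce")
    bad = df.index[times.isna() | (times <= 0)]
    if len(bad):
        raise SplitDataError(
            f"non-positive or non-numeric lap_time_s at row(s) {list(bad[:5])}"
        )
    df = df.assign(lap_time_s=times)

    dup = df.duplicated(subset=["runner_id", "day", "lap"])
    if dup.any():
        first = df.loc[dup, ["runner_id", "day", "lap"]].iloc[0]
        raise SplitDataError(
            f"duplicate (runner, day, lap) = "
            f"({first.runner_id!r}, {first.day}, {first.lap})"
        )

    records = []
    expected = np.arange(1, course.n_laps + 1)
    for (rid, day), grp in df.groupby(["runner_id", "day"], sort=True):
        grp = grp.sort_values("lap")
        if len(grp) != course.n_laps or not np.array_equal(
            grp["lap"].to_numpy(), expected
        ):
            warnings.warn(
                f"runner {rid!r} day {day}: expected laps 1..{course.n_laps}, "
                f"got {len(grp)} rows; record excluded",
                stacklevel=2,
            )
            continue
        records.append(
            RaceRecord(
                runner_id=str(rid),
                day=int(day),
                course=course,
                lap_times=grp["lap_time_s"].to_numpy(dtype=float),
            )
        )
    return Cohort(records)


def write_split_table(cohort: Cohort, path) -> None:
    """Write a cohort back to the long-format CSV dialect."""
    rows = []
    for rec in cohort:
        for k, t in enumerate(rec.lap_times, start=1):
            rows.append((rec.runner_id, rec.day, k, t))
    pd.DataFrame(rows, columns=list(SPLIT_COLUMNS)).to_csv(path, index=False)


def lap_speeds(record: RaceRecord) -> np.ndarray:
    """Per-lap mean speeds, m/s."""
    return record.course.lap_distance / record.lap_times


def race_mean_speed(record: RaceRecord) -> float:
    """Whole-race mean speed: distance over finish time (time-weighted)."""
    return record.course.total_distance / record.total_time


def time_at_distance(record: RaceRecord, x: float) -> float:
    """Cumulative time (s) to reach distance ``x``, assuming constant speed
    within each lap (linear interpolation in distance)."""
    d = record.course.lap_distance
    total = record.course.total_distance
    if not 0 <= x <= total * (1 + 1e-12):
        raise ValueError(f"distance {x} outside [0, {total}]")
    x = min(x, total)
    n_full = min(int(math.floor(x / d)), record.course.n_laps)
    t = float(record.lap_times[:n_full].sum())
    frac = x / d - n_full
    if frac > 0 and n_full < record.course.n_laps:
        t += frac * float(record.lap_times[n_full])
    return t


def segment_mean_speed(record: RaceRecord, x_start: float, x_end: float) -> float:
    """Mean speed over the course segment [x_start, x_end] in metres."""
    if not x_start < x_end:
        raise ValueError("segment must have x_start < x_end")
    dt = time_at_distance(record, x_end) - time_at_distance(record, x_start)
    return (x_end - x_start) / dt
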
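"""The eight per-race pacing statistics.

Each race yields a mean speed (MS) plus seven dimensionless variables that
quantify departure from even pacing, all expressed in percent:

* CV  — sd of lap speeds over race mean speed,
* CS  — mean signed lap deviation from race mean speed,
* CSF — mean lap deviation from the first-lap speed,
* ACS — mean absolute lap deviation from race mean speed,
* PR  — fastest-lap excess plus slowest-lap deficit (pace range),
* MRS — first-half vs second-half speed change,
* 32-10 — first-32 km vs last-10 km speed change.

CSF, MRS and 32-10 compare an earlier to a later segment; by default they use
the *slowdown-positive* convention (earlier speed minus later, over earlier),
so a fading runner — the typical positive pacer — scores positive.  Pass
``sign="literal"`` for the opposite (later-minus-earlier) reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .race_model import Cohort, RaceRecord, lap_speeds, race_mean_speed, segment_mean_speed

__all__ = [
    "PacingVariables",
    "coefficient_of_variation",
    "change_in_mean_speed",
    "change_first_lap",
    "absolute_change",
    "pace_range",
    "mid_race_split",
    "split_32_10",
    "compute_all",
    "cohort_variables",
]

#: Canonical variable order used in tables and reports.
VARIABLE_NAMES = ("ms", "cv", "cs", "csf", "acs", "pr", "mrs", "split_32_10")

_SIGNS = ("slowdown-positive", "literal")


def _check_sign(sign: str) -> None:
    if sign not in _SIGNS:
        raise ValueError(f"sign must be one of {_SIGNS}, got {sign!r}")


@dataclass(frozen=True)
class PacingVariables:
    """All per-race statistics for one runner-day, percentages except ``ms``."""

    ms: float
    cv: float
    cs: float
    csf: float
    acs: float
    positive_range: float
    negative_range: float
    pr: float
    mrs: float
    split_32_10: float


def coefficient_of_variation(record: RaceRecord) -> float:
    """CV: 100 * sample sd of lap speeds / race mean speed."""
    v = lap_speeds(record)
    if len(v) < 2:
        raise ValueError("CV needs at least 2 laps")
    return 100.0 * float(np.std(v, ddof=1)) / race_mean_speed(record)


def change_in_mean_speed(record: RaceRecord) -> float:
    """CS: mean signed percent deviation of lap speed from race mean speed.

    Always >= 0: the arithmetic (distance-weighted) mean of lap speeds cannot
    fall below the time-weighted race mean speed.
    """
    v = lap_speeds(record)
    vbar = race_mean_speed(record)
    return 100.0 * float(np.mean(v - vbar)) / vbar


def change_first_lap(record: RaceRecord, sign: str = "slowdown-positive") -> float:
    """CSF: mean percent deviation of each lap's speed from the first lap's.

    Lap 1 contributes 0 to the mean.  Slowdown-positive by default: laps
    slower than lap 1 push CSF up.
    """
    _check_sign(sign)
    v = lap_speeds(record)
    val = 100.0 * float(np.mean((v[0] - v) / v[0]))
    return val if sign == "slowdown-positive" else -val


def absolute_change(record: RaceRecord) -> float:
    """ACS: mean absolute percent deviation of lap speed from race mean speed."""
    v = lap_speeds(record)
    vbar = race_mean_speed(record)
    return 100.0 * float(np.mean(np.abs(v - vbar))) / vbar


def pace_range(record: RaceRecord) -> tuple[float, float, float]:
    """(positive_range, negative_range, PR).

    Positive range: percent by which the fastest lap exceeds race mean speed;
    negative range: percent by which the slowest falls below it; PR is their
    sum, i.e. 100 * (max v - min v) / race mean speed.
    """
    v = lap_speeds(record)
    vbar = race_mean_speed(record)
    pos = 100.0 * (float(v.max()) - vbar) / vbar
    neg = 100.0 * (vbar - float(v.min())) / vbar
    return pos, neg, pos + neg


def mid_race_split(record: RaceRecord, sign: str = "slowdown-positive") -> float:
    """MRS: percent speed change between the two distance halves of the race.

    Halves are defined by distance (D/2) with within-lap interpolation, since
    an odd lap count has no mid lap.
    """
    _check_sign(sign)
    half = record.course.total_distance / 2.0
    v1 = segment_mean_speed(record, 0.0, half)
    v2 = segment_mean_speed(record, half, record.course.total_distance)
    val = 100.0 * (v1 - v2) / v1
    return val if sign == "slowdown-positive" else -val


def split_32_10(record: RaceRecord, sign: str = "slowdown-positive") -> float:
    """32-10 split: percent speed change of the last 10 km vs the prior race.

    The boundary sits at D - 10,000 m (32,195 m on a marathon), interpolated
    within the containing lap.
    """
    _check_sign(sign)
    D = record.course.total_distance
    if D <= 10000.0:
        raise ValueError("32-10 split needs a course longer than 10 km")
    b = D - 10000.0
    v1 = segment_mean_speed(record, 0.0, b)
    v2 = segment_mean_speed(record, b, D)
    val = 100.0 * (v1 - v2) / v1
    return val if sign == "slowdown-positive" else -val


def compute_all(record: RaceRecord, sign: str = "slowdown-positive") -> PacingVariables:
    """All pacing variables for one race, consistent with the single-metric
    functions above.  On a course of 10 km or less the 32-10 split is
    undefined and reported as NaN."""
    pos, neg, pr = pace_range(record)
    s3210 = (
        split_32_10(record, sign)
        if record.course.total_distance > 10000.0
        else float("nan")
    )
    return PacingVariables(
        ms=race_mean_speed(record),
        cv=coefficient_of_variation(record),
        cs=change_in_mean_speed(record),
        csf=change_first_lap(record, sign),
        acs=absolute_change(record),
        positive_range=pos,
        negative_range=neg,
        pr=pr,
        mrs=mid_race_split(record, sign),
        split_32_10=s3210,
    )


def cohort_variables(cohort: Cohort, sign: str = "slowdown-positive") -> pd.DataFrame:
    """Tidy per-(runner, day) table of all pacing variables.

    Columns: runner_id, day, ms, cv, cs, csf, acs, positive_range,
    negative_range, pr, mrs, split_32_10; one row per record, sorted by
    (runner_id, day).
    """
    rows = []
    for rec in cohort:
        pv = compute_all(rec, sign)
        rows.append({"runner_id": rec.runner_id, "day": rec.day, **vars(pv)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["runner_id", "day"], ignore_index=True)
    return df
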
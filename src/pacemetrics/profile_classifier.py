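"""Per-race pacing-profile regression and day-to-day profile consistency.

A race's pacing profile is summarised by the ordinary least-squares fit of
lap speed against lap index.  The Pearson correlation r of that fit labels
the profile: ``positive`` pacing (slowing over the race) for r < -0.1,
``negative`` (speeding up) for r > 0.1, and ``even`` for -0.1 <= r <= 0.1
(boundaries classify as even).  Fisher's Z transform linearises r for the
repeated-measures ANOVA across days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .race_model import Cohort, RaceRecord, lap_speeds
from .reliability import rm_anova

__all__ = [
    "PacingProfile",
    "ConsistencySummary",
    "classify_r",
    "regression_profile",
    "fisher_z",
    "cohort_profiles",
    "profile_consistency",
    "rm_anova_on_z",
]

#: |r| <= EVEN_THRESHOLD labels a race as even-paced.
EVEN_THRESHOLD = 0.1

#: |r| is clamped here before the Fisher transform (atanh diverges at 1).
R_MAX = 0.999999


@dataclass(frozen=True)
class PacingProfile:
    """OLS summary of one race's lap-speed trend."""

    slope: float  # (m/s) per lap
    r: float
    z: float
    label: str  # "even" | "positive" | "negative"
    degenerate: bool = False


@dataclass(frozen=True)
class ConsistencySummary:
    """How stable each runner's profile label is across days."""

    label_counts: pd.DataFrame  # runners x labels count table
    frac_identical_all_days: float
    frac_identical_all_but_one: float


def classify_r(r: float) -> str:
    """Label a profile from its lap-speed-vs-lap-index correlation."""
    if r < -EVEN_THRESHOLD:
        return "positive"
    if r > EVEN_THRESHOLD:
        return "negative"
    return "even"


def fisher_z(r: float) -> float:
    """Fisher Z = atanh(r); |r| >= 1 is clamped to +-0.999999 with a warning."""
    if abs(r) >= 1.0:
        warnings.warn(f"|r| = {abs(r)} >= 1 clamped to {R_MAX}", stacklevel=2)
        r = np.sign(r) * R_MAX
    return float(np.arctanh(r))


def regression_profile(record: RaceRecord) -> PacingProfile:
    """Fit lap speed against lap index (1..n) and classify the trend.

    A zero-variance record (all laps identical) has no defined correlation;
    it is reported as r = 0, label even, flagged degenerate.
    """
    v = lap_speeds(record)
    if len(v) < 3:
        raise ValueError("profile regression needs at least 3 laps")
    k = np.arange(1, len(v) + 1, dtype=float)
    if np.ptp(v) == 0.0:
        return PacingProfile(slope=0.0, r=0.0, z=0.0, label="even", degenerate=True)
    fit = stats.linregress(k, v)
    r = float(fit.rvalue)
    return PacingProfile(
        slope=float(fit.slope), r=r, z=fisher_z(r), label=classify_r(r)
    )


def cohort_profiles(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-(runner, day) profile table: runner_id, day, slope, r, z,
    label, degenerate."""
    rows = []
    for rec in cohort:
        p = regression_profile(rec)
        rows.append({"runner_id": rec.runner_id, "day": rec.day, **vars(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["runner_id", "day"], ignore_index=True)
    return df


def profile_consistency(profiles: pd.DataFrame) -> ConsistencySummary:
    """Fraction of runners keeping the same label on all days / all but one.

    ``profiles`` must contain one labelled row per (runner, day) for every
    runner-day combination.
    """
    n_days = profiles["day"].nunique()
    per_runner = profiles.groupby("runner_id")["label"]
    if (per_runner.count() != n_days).any():
        raise ValueError("every runner needs a profile for every day")
    counts = (
        profiles.groupby(["runner_id", "label"]).size().unstack(fill_value=0)
    )
    top = counts.max(axis=1)
    n_runners = len(counts)
    frac_all = float((top == n_days).sum()) / n_runners
    frac_but_one = float((top == n_days - 1).sum()) / n_runners
    return ConsistencySummary(
        label_counts=counts,
        frac_identical_all_days=frac_all,
        frac_identical_all_but_one=frac_but_one,
    )


def rm_anova_on_z(z_matrix) -> tuple[float, float]:
    """Repeated-measures ANOVA on the Fisher-Z profile coefficients.

    ``z_matrix`` is runners x days, complete.  Returns (F, p) for the day
    effect on df (k-1, (n-1)(k-1)); no sphericity correction.
    """
    a = rm_anova(z_matrix)
    return a.f, a.p


def z_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """Pivot the tidy profile table into a complete runners x days Fisher-Z
    matrix."""
    wide = profiles.pivot(index="runner_id", columns="day", values="z")
    if wide.isna().any().any():
        raise ValueError("incomplete runner-day grid of profiles")
    return wide.to_numpy(dtype=float)
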
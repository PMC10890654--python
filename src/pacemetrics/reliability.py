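"""Day-to-day test-retest reliability battery.

Works on a complete runners-by-days measurement matrix of one variable and
produces the classic repeated-performance reliability panel: repeated-measures
ANOVA (day effect), ICC with a 95% CI, standard error of measurement (SEM),
and the typical-error coefficient of variation (CV%) via the 100*ln transform
with back-transformation.

The ICC defaults to the two-way mixed-effects, single-measure, *consistency*
form, ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error),
the standard choice when the same athletes repeat the same performance and a
systematic day shift should not count against reliability.  ICC(2,1)
(absolute agreement) is available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pacing_metrics import VARIABLE_NAMES

__all__ = [
    "RMAnova",
    "ReliabilityStats",
    "rm_anova",
    "icc_3_1",
    "icc_2_1",
    "sem",
    "typical_error_cv",
    "icc_interpretation",
    "measurement_matrix",
    "reliability_report",
    "reliability_table",
]


@dataclass(frozen=True)
class RMAnova:
    """Two-way decomposition of a subjects x days matrix (no replication)."""

    ss_rows: float
    ss_cols: float
    ss_error: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int
    f: float
    p: float

    @property
    def ss_total(self) -> float:
        return self.ss_rows + self.ss_cols + self.ss_error


@dataclass(frozen=True)
class ReliabilityStats:
    """Reliability panel for one variable."""

    variable: str
    day_means: np.ndarray
    day_sds: np.ndarray
    cv_percent: float
    sem: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    f_stat: float
    p_value: float
    transform_used: str  # "log" or "raw"
    interpretation: str


def _as_matrix(values) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 runners and >= 2 days")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains missing or non-finite cells")
    return x


def rm_anova(values) -> RMAnova:
    """One-way repeated-measures ANOVA (subjects = rows, within factor = cols).

    F tests the column (day) effect: F = MS_cols / MS_error on
    df (k-1, (n-1)(k-1)).  No sphericity correction is applied.
    """
    x = _as_matrix(values)
    n, k = x.shape
    grand = x.mean()
    ss_rows = k * float(((x.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((x.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    # exact zeros survive cancellation: drop components that are pure
    # floating-point residue relative to the total variation
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_cols < tol:
        ss_cols = 0.0
    if ss_error < tol:
        ss_error = 0.0
    df_rows, df_cols = n - 1, k - 1
    df_error = df_rows * df_cols
    ms_rows = ss_rows / df_rows
    ms_cols = ss_cols / df_cols
    ms_error = ss_error / df_error
    if ms_error == 0.0:
        if ms_cols == 0.0:
            f, p = 0.0, 1.0
        else:
            warnings.warn("zero error variance: F reported as infinite", stacklevel=2)
            f, p = np.inf, 0.0
    else:
        f = ms_cols / ms_error
        p = float(stats.f.sf(f, df_cols, df_error))
    return RMAnova(
        ss_rows, ss_cols, ss_error, ms_rows, ms_cols, ms_error,
        df_rows, df_cols, df_error, float(f), p,
    )


def icc_3_1(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(3,1): two-way mixed effects, single measure, consistency.

    Returns (icc, ci_low, ci_high); the CI comes from the closed-form F
    bounds on F = MS_subjects / MS_error with df (n-1, (n-1)(k-1)).
    """
    x = _as_matrix(values)
    n, k = x.shape
    a = rm_anova(x)
    denom = a.ms_rows + (k - 1) * a.ms_error
    if denom == 0.0:
        raise ValueError("ICC undefined: no variance in the matrix")
    icc = (a.ms_rows - a.ms_error) / denom
    alpha = 1.0 - confidence
    if a.ms_error == 0.0:
        return float(icc), float(icc), float(icc)
    f_obs = a.ms_rows / a.ms_error
    fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, a.df_error)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, a.df_error, n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), float(lo), float(hi)


def icc_2_1(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    CI bounds follow the McGraw & Wong construction (Satterthwaite df for the
    day-effect term).
    """
    x = _as_matrix(values)
    n, k = x.shape
    a = rm_anova(x)
    msr, msc, mse = a.ms_rows, a.ms_cols, a.ms_error
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValueError("ICC undefined: no variance in the matrix")
    icc = (msr - mse) / denom
    alpha = 1.0 - confidence
    if mse == 0.0 and msc == 0.0:
        return float(icc), float(icc), float(icc)
    a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b_ = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a_):
        return float(icc), float(icc), float(icc)
    num_v = (a_ * msc + b_ * mse) ** 2
    den_v = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v
    f_star_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_star_lo * mse) / (
        f_star_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_star_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star_hi * msr
    )
    return float(icc), float(lo), float(hi)


def sem(values, icc: float) -> float:
    """Standard error of measurement: pooled sd * sqrt(1 - ICC).

    The pooled sd is taken over all cells after removing day means (consistent
    with the consistency ICC: a uniform day shift does not inflate it).
    """
    x = _as_matrix(values)
    n, k = x.shape
    resid = x - x.mean(axis=0, keepdims=True)
    pooled_var = float((resid**2).sum()) / (n * k - k)
    return float(np.sqrt(pooled_var) * np.sqrt(max(1.0 - icc, 0.0)))


def typical_error_cv(values) -> tuple[float, str]:
    """Typical-error CV% via the 100*ln transform, back-transformed.

    Runs the repeated-measures ANOVA on 100*ln(x); the typical error is
    s = sqrt(MS_error) and CV% = 100*(exp(s/100) - 1).  If any cell is <= 0
    (possible for signed variables such as CS under a negative split) the log
    path is impossible; falls back to the raw-scale typical error divided by
    the grand mean, flagged ``"raw"``.

    Returns (cv_percent, transform_used).
    """
    x = _as_matrix(values)
    if np.all(x > 0):
        a = rm_anova(100.0 * np.log(x))
        s = np.sqrt(a.ms_error)
        return 100.0 * float(np.expm1(s / 100.0)), "log"
    a = rm_anova(x)
    s = float(np.sqrt(a.ms_error))
    grand = abs(float(x.mean()))
    if grand == 0.0:
        return np.inf if s > 0 else 0.0, "raw"
    return 100.0 * s / grand, "raw"


def icc_interpretation(icc: float) -> str:
    """Conventional reliability bands: poor < 0.5 <= moderate < 0.75 <= good
    < 0.9 <= excellent."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def measurement_matrix(variables: pd.DataFrame, variable: str) -> np.ndarray:
    """Pivot the tidy per-(runner, day) variable table into a complete
    runners x days matrix for one variable."""
    wide = variables.pivot(index="runner_id", columns="day", values=variable)
    if wide.isna().any().any():
        raise ValueError(f"incomplete runner-day grid for variable {variable!r}")
    return wide.to_numpy(dtype=float)


def reliability_report(
    variables: pd.DataFrame,
    icc_form: str = "3,1",
    variable_names=VARIABLE_NAMES,
) -> list[ReliabilityStats]:
    """Full reliability panel, one :class:`ReliabilityStats` per variable.

    ``variables`` is the tidy table from
    :func:`pacemetrics.pacing_metrics.cohort_variables`, restricted to
    complete runners.  ``icc_form`` is ``"3,1"`` (consistency, default) or
    ``"2,1"`` (absolute agreement).
    """
    icc_fn = {"3,1": icc_3_1, "2,1": icc_2_1}.get(icc_form)
    if icc_fn is None:
        raise ValueError("icc_form must be '3,1' or '2,1'")
    out = []
    for name in variable_names:
        x = measurement_matrix(variables, name)
        a = rm_anova(x)
        if a.ms_rows == 0.0 and a.ms_error == 0.0:
            # zero-variance variable (e.g. an even-paced degenerate cohort)
            out.append(
                ReliabilityStats(
                    variable=name,
                    day_means=x.mean(axis=0),
                    day_sds=x.std(axis=0, ddof=1),
                    cv_percent=0.0,
                    sem=0.0,
                    icc=np.nan,
                    icc_ci_low=np.nan,
                    icc_ci_high=np.nan,
                    f_stat=a.f,
                    p_value=a.p,
                    transform_used="raw",
                    interpretation="undefined (zero variance)",
                )
            )
            continue
        icc, lo, hi = icc_fn(x)
        cv_pct, transform = typical_error_cv(x)
        out.append(
            ReliabilityStats(
                variable=name,
                day_means=x.mean(axis=0),
                day_sds=x.std(axis=0, ddof=1),
                cv_percent=cv_pct,
                sem=sem(x, icc),
                icc=icc,
                icc_ci_low=lo,
                icc_ci_high=hi,
                f_stat=a.f,
                p_value=a.p,
                transform_used=transform,
                interpretation=icc_interpretation(icc),
            )
        )
    return out


def reliability_table(stats_list: list[ReliabilityStats]) -> pd.DataFrame:
    """Flatten a reliability panel into a report DataFrame (one variable per
    row, one ``dayN_mean``/``dayN_sd`` column pair per day)."""
    rows = []
    for s in stats_list:
        row = {"variable": s.variable}
        for d, (m, sd_) in enumerate(zip(s.day_means, s.day_sds), start=1):
            row[f"day{d}_mean"] = m
            row[f"day{d}_sd"] = sd_
        row.update(
            cv_percent=s.cv_percent,
            sem=s.sem,
            icc=s.icc,
            icc_ci_low=s.icc_ci_low,
            icc_ci_high=s.icc_ci_high,
            f=s.f_stat,
            p=s.p_value,
            transform_used=s.transform_used,
            interpretation=s.interpretation,
        )
        rows.append(row)
    return pd.DataFrame(rows)
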
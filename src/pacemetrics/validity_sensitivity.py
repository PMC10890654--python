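"""Concurrent validity, sensitivity, and performance-group comparisons.

Validity: each pacing variable is correlated per day against the CV, the
conventional gold standard for variability.  Sensitivity: the reliable
variables (CV, ACS, PR by default) are correlated against race mean speed —
slower runners pace more variably, so a useful variable should correlate
negatively — and compared between Fast/Medium/Slow performance groups with a
one-way ANOVA, eta-squared effect size, and unadjusted LSD pairwise t-tests
on the pooled error term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "GroupAssignment",
    "GroupComparison",
    "pearson",
    "validity_table",
    "sensitivity_correlations",
    "bin_performance_groups",
    "oneway_anova_lsd",
    "group_comparison_table",
]

VALIDITY_VARIABLES = ("cs", "csf", "acs", "pr", "mrs", "split_32_10")

#: Variables reliable enough for the sensitivity battery (the signed and
#: two-point variables are excluded by default for their poor test-retest
#: reliability; override with the ``variables`` argument).
SENSITIVITY_VARIABLES = ("cv", "acs", "pr")

GROUP_ORDER = ("Fast", "Medium", "Slow")

#: Default explicit group boundaries, seconds (4:01:17 and 4:37:08).
DEFAULT_BOUNDARIES = (4 * 3600 + 1 * 60 + 17, 4 * 3600 + 37 * 60 + 8)


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    day: int
    r: float
    p_value: float
    n: int
    interpretation: str


@dataclass(frozen=True)
class GroupAssignment:
    runner_id: str
    group: str
    mean_marathon_time: float


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    day: int
    f: float
    p: float
    eta_squared: float
    group_means: dict = field(default_factory=dict)
    lsd_p: dict = field(default_factory=dict)  # (group_a, group_b) -> p


def correlation_interpretation(r: float) -> str:
    """Conventional magnitude bands: small 0.10, moderate 0.30, large 0.50."""
    a = abs(r)
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "moderate"
    if a >= 0.1:
        return "small"
    return "trivial"


def pearson(x, y, x_name: str = "x", y_name: str = "y", day: int = 0) -> CorrelationResult:
    """Pearson correlation with the two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("Pearson r undefined for a zero-variance vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        day=day,
        r=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
        interpretation=correlation_interpretation(float(res.statistic)),
    )


def _per_day_correlations(variables: pd.DataFrame, xs, y_name: str):
    days = sorted(variables["day"].unique())
    out = []
    for day in days:
        sub = variables[variables["day"] == day].sort_values("runner_id")
        for x_name in xs:
            out.append(
                pearson(sub[x_name], sub[y_name], x_name=x_name, y_name=y_name, day=day)
            )
    return out


def validity_table(variables: pd.DataFrame, xs=VALIDITY_VARIABLES) -> list[CorrelationResult]:
    """Per-day Pearson correlations of each pacing variable against CV."""
    return _per_day_correlations(variables, xs, "cv")


def sensitivity_correlations(
    variables: pd.DataFrame, xs=SENSITIVITY_VARIABLES
) -> list[CorrelationResult]:
    """Per-day Pearson correlations of the reliable variables against mean
    speed."""
    return _per_day_correlations(variables, xs, "ms")


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df["significance"] = np.where(
            df["p_value"] < 0.01, "**", np.where(df["p_value"] < 0.05, "*", "")
        )
    return df


def bin_performance_groups(
    mean_times: pd.Series,
    method: str = "boundaries",
    boundaries: tuple[float, float] = DEFAULT_BOUNDARIES,
) -> list[GroupAssignment]:
    """Assign runners to Fast/Medium/Slow performance groups.

    ``mean_times`` maps runner_id -> mean marathon time (s) over the days.

    * ``boundaries``: times <= boundaries[0] are Fast, <= boundaries[1]
      Medium, else Slow.
    * ``tertile``: rank by mean time and split as evenly as possible, the
      earlier groups taking the extra runner; ties broken by runner id.
    """
    if len(mean_times) < 3:
        raise ValueError("need at least 3 runners to form 3 groups")
    if method == "boundaries":
        t1, t2 = boundaries
        if not t1 < t2:
            raise ValueError("boundaries must be increasing")
        out = []
        for rid, t in mean_times.items():
            group = "Fast" if t <= t1 else ("Medium" if t <= t2 else "Slow")
            out.append(GroupAssignment(str(rid), group, float(t)))
        return out
    if method == "tertile":
        order = sorted(mean_times.items(), key=lambda kv: (kv[1], str(kv[0])))
        n = len(order)
        base, extra = divmod(n, 3)
        sizes = [base + (1 if i < extra else 0) for i in range(3)]
        out = []
        idx = 0
        for group, size in zip(GROUP_ORDER, sizes):
            for rid, t in order[idx : idx + size]:
                out.append(GroupAssignment(str(rid), group, float(t)))
            idx += size
        return out
    raise ValueError("method must be 'boundaries' or 'tertile'")


def oneway_anova_lsd(
    values: pd.Series, groups: list[GroupAssignment], variable: str = "", day: int = 0
) -> GroupComparison:
    """One-way between-groups ANOVA with eta-squared and LSD post-hoc.

    ``values`` maps runner_id -> the variable's value.  The LSD procedure is
    pairwise t-tests on the pooled within-group mean square with its df,
    deliberately unadjusted.
    """
    by_group: dict[str, list[float]] = {}
    for ga in groups:
        if ga.runner_id in values.index:
            by_group.setdefault(ga.group, []).append(float(values[ga.runner_id]))
    present = [g for g in GROUP_ORDER if g in by_group]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty groups")
    for g in present:
        if len(by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")
    samples = [np.asarray(by_group[g]) for g in present]
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ss_total = ss_between + ss_within
    df_b = len(present) - 1
    df_w = len(all_vals) - len(present)
    mse = ss_within / df_w
    if mse == 0.0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / mse
        p = float(stats.f.sf(f, df_b, df_w))
    eta2 = float(ss_between / ss_total) if ss_total > 0 else 0.0

    lsd = {}
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            a, b = samples[i], samples[j]
            if mse == 0.0:
                lsd[(present[i], present[j])] = 1.0 if a.mean() == b.mean() else 0.0
                continue
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = (a.mean() - b.mean()) / se
            lsd[(present[i], present[j])] = float(2 * stats.t.sf(abs(t), df_w))

    return GroupComparison(
        variable=variable,
        day=day,
        f=float(f),
        p=p,
        eta_squared=eta2,
        group_means={g: float(np.mean(by_group[g])) for g in present},
        lsd_p=lsd,
    )


def group_comparison_table(
    variables: pd.DataFrame,
    groups: list[GroupAssignment],
    which=SENSITIVITY_VARIABLES,
) -> pd.DataFrame:
    """Per-day group comparison for each sensitivity variable, flattened to a
    report DataFrame."""
    rows = []
    for day in sorted(variables["day"].unique()):
        sub = variables[variables["day"] == day].set_index("runner_id")
        for var in which:
            gc = oneway_anova_lsd(sub[var], groups, variable=var, day=day)
            row = {
                "variable": var,
                "day": day,
                "f": gc.f,
                "p": gc.p,
                "eta_squared": gc.eta_squared,
            }
            for g, m in gc.group_means.items():
                row[f"mean_{g}"] = m
            for (a, b), p in gc.lsd_p.items():
                row[f"lsd_p_{a}_vs_{b}"] = p
            rows.append(row)
    return pd.DataFrame(rows)


def mean_marathon_times(variables: pd.DataFrame, course_distance: float = 42195.0) -> pd.Series:
    """Per-runner mean finish time (s) over all days, from the tidy variable
    table's mean-speed column."""
    times = course_distance / variables.set_index("runner_id")["ms"]
    return times.groupby(level=0).mean().sort_index()
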
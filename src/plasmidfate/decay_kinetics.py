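"""Log-linear decay kinetics for marker-gene abundance time series.

Concentrations (gene copies per gram dry weight) are transformed to
``log10(Ct / C0)`` and fitted by ordinary least squares, either as a single
segment or as two independent segments split at a breakpoint day (biphasic
decay: a fast thermophilic phase followed by a slow phase or a rebound).
The decimal reduction time (D-value) is the time for a one-log10 drop,
``|1 / slope|`` of a fitted segment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecayFit",
    "GroupComparison",
    "log_ratio",
    "fit_linear_decay",
    "fit_biphasic",
    "removal_efficiency",
    "abundance_ratio",
    "compare_groups",
    "fit_decay_table",
]


@dataclass(frozen=True)
class DecayFit:
    """One fitted log-linear decay segment.

    ``slope`` is in log10 copies per day; ``d_value`` is ``|1/slope|`` days
    for a negative slope and ``inf`` for a flat or increasing segment.
    """

    gene: str = ""
    treatment: str = ""
    segment_label: str = "single"
    day_range: tuple[float, float] = (0.0, 0.0)
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    d_value: float = float("nan")
    n_points: int = 0
    rss: float = float("nan")


@dataclass
class GroupComparison:
    """One-way ANOVA plus post-hoc pairwise comparisons for grouped values."""

    groups: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    anova_f: float
    anova_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, mark
    method: str
    note: str = ""


def log_ratio(ct: float, c0: float) -> float:
    """log10 of the abundance ratio ``Ct / C0``; negative under decay.

    Raises ``ValueError`` on non-positive inputs — below-detection values
    must be handled (excluded or substituted) by the caller.
    """
    if ct <= 0 or c0 <= 0:
        raise ValueError(f"log_ratio requires positive concentrations, got ct={ct}, c0={c0}")
    return math.log10(ct / c0)


def removal_efficiency(c0: float, ct: float) -> float:
    """Percent of the initial abundance removed, ``100 * (1 - Ct/C0)``.

    Negative values indicate net growth (``Ct > C0``).
    """
    if c0 <= 0:
        raise ValueError(f"removal_efficiency requires c0 > 0, got {c0}")
    if ct < 0:
        raise ValueError(f"removal_efficiency requires ct >= 0, got {ct}")
    return 100.0 * (1.0 - ct / c0)


def abundance_ratio(treatment_a_ct: float, treatment_b_ct: float) -> float:
    """Abundance in one treatment as a percentage of another, ``100 * a / b``."""
    if treatment_b_ct <= 0:
        raise ValueError("abundance_ratio requires a positive denominator")
    if treatment_a_ct < 0:
        raise ValueError("abundance_ratio requires a non-negative numerator")
    return 100.0 * treatment_a_ct / treatment_b_ct


def _ols_fit(
    days: np.ndarray,
    log_ratios: np.ndarray,
    *,
    gene: str,
    treatment: str,
    segment_label: str,
) -> DecayFit:
    slope, intercept = np.polyfit(days, log_ratios, 1)
    fitted = slope * days + intercept
    rss = float(np.sum((log_ratios - fitted) ** 2))
    tss = float(np.sum((log_ratios - log_ratios.mean()) ** 2))
    # r^2 of a constant series against a fitted constant is 1 by convention
    r_squared = 1.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    d_value = abs(1.0 / slope) if slope < 0 else float("inf")
    return DecayFit(
        gene=gene,
        treatment=treatment,
        segment_label=segment_label,
        day_range=(float(days.min()), float(days.max())),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(min(r_squared, 1.0)),
        d_value=d_value,
        n_points=len(days),
        rss=rss,
    )


def fit_linear_decay(
    days: Sequence[float],
    log_ratios: Sequence[float],
    *,
    gene: str = "",
    treatment: str = "",
    segment_label: str = "single",
) -> DecayFit:
    """Ordinary least squares of ``log10(Ct/C0)`` against time.

    Requires at least two distinct days. The D-value is ``|1/slope|`` days
    when the slope is negative, ``inf`` otherwise.
    """
    days_arr = np.asarray(days, dtype=float)
    lr_arr = np.asarray(log_ratios, dtype=float)
    if days_arr.shape != lr_arr.shape:
        raise ValueError("days and log_ratios must have equal length")
    if len(days_arr) < 2:
        raise ValueError("need at least 2 points for a linear fit")
    if np.unique(days_arr).size < 2:
        raise ValueError("need at least 2 distinct days for a linear fit")
    return _ols_fit(days_arr, lr_arr, gene=gene, treatment=treatment, segment_label=segment_label)


def fit_biphasic(
    days: Sequence[float],
    log_ratios: Sequence[float],
    breakpoint_day: float = 15.0,
    *,
    search_breakpoint: bool = False,
    gene: str = "",
    treatment: str = "",
) -> tuple[DecayFit, DecayFit]:
    """Fit two independent OLS segments split at a breakpoint day.

    The breakpoint day itself belongs to phase I. With
    ``search_breakpoint=True`` the breakpoint is chosen among the observed
    sampling days by minimizing the total residual sum of squares
    (``breakpoint_day`` is then ignored). During the search the candidate
    breakpoint day anchors *both* segments — for a continuous piecewise
    line the kink sample lies on both branches, and sharing it is what
    makes the true breakpoint identifiable; the returned fits then use the
    partition convention (breakpoint day in phase I only).
    """
    days_arr = np.asarray(days, dtype=float)
    lr_arr = np.asarray(log_ratios, dtype=float)
    if days_arr.shape != lr_arr.shape:
        raise ValueError("days and log_ratios must have equal length")
    order = np.argsort(days_arr, kind="stable")
    days_arr, lr_arr = days_arr[order], lr_arr[order]

    def split_fit(bp: float) -> tuple[DecayFit, DecayFit]:
        left = days_arr <= bp
        right = ~left
        if np.unique(days_arr[left]).size < 2 or np.unique(days_arr[right]).size < 2:
            raise ValueError(
                f"breakpoint {bp} leaves fewer than 2 distinct days in a segment"
            )
        f1 = _ols_fit(days_arr[left], lr_arr[left], gene=gene, treatment=treatment,
                      segment_label="phase I")
        f2 = _ols_fit(days_arr[right], lr_arr[right], gene=gene, treatment=treatment,
                      segment_label="phase II")
        return f1, f2

    if not search_breakpoint:
        if breakpoint_day < days_arr.min() or breakpoint_day >= days_arr.max():
            raise ValueError(
                f"breakpoint {breakpoint_day} outside observed day range "
                f"[{days_arr.min()}, {days_arr.max()})"
            )
        return split_fit(breakpoint_day)

    unique_days = np.unique(days_arr)
    candidates = [
        d for d in unique_days
        if (unique_days <= d).sum() >= 2 and (unique_days > d).sum() >= 2
    ]
    if not candidates:
        raise ValueError("no candidate breakpoint leaves 2 distinct days per segment")

    def anchored_rss(bp: float) -> float:
        left = days_arr <= bp
        right = days_arr >= bp  # breakpoint sample shared by both branches
        rss = 0.0
        for mask in (left, right):
            s, i = np.polyfit(days_arr[mask], lr_arr[mask], 1)
            rss += float(np.sum((lr_arr[mask] - (s * days_arr[mask] + i)) ** 2))
        return rss

    best = min(candidates, key=anchored_rss)
    return split_fit(best)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    method: str = "tukey",
) -> GroupComparison:
    """One-way ANOVA followed by Tukey HSD pairwise comparisons.

    ``method="duncan"`` is accepted but computed as Tukey HSD (a slightly
    conservative surrogate for Duncan's multiple range test); the result
    carries a note saying so. Significance marks: ``**`` for p < 0.01,
    ``*`` for p < 0.05.
    """
    if method not in ("tukey", "duncan"):
        raise ValueError(f"unknown method {method!r}")
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    for g, a in zip(groups, arrays):
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    anova_f, anova_p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        p = float(res.pvalue[i, j])
        mark = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append({"group_a": groups[i], "group_b": groups[j], "p_adj": p, "mark": mark})
    note = "Duncan's test approximated by Tukey HSD" if method == "duncan" else ""
    return GroupComparison(
        groups=groups,
        means={g: float(a.mean()) for g, a in zip(groups, arrays)},
        sds={g: float(a.std(ddof=1)) for g, a in zip(groups, arrays)},
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        pairwise=pd.DataFrame(rows),
        method="tukey",
        note=note,
    )


def fit_decay_table(
    abundance: pd.DataFrame,
    *,
    genes: Sequence[str] = ("dsRed", "gfp"),
    breakpoint_day: float | None = 15.0,
    per_replicate: bool = True,
    search_breakpoint: bool = False,
) -> pd.DataFrame:
    """Fit decay segments for every (treatment, gene[, replicate]) series.

    ``abundance`` is a long-format table with columns ``treatment``,
    ``replicate``, ``day``, ``gene`` and ``copies_per_g_dw``. Each series is
    transformed to ``log10(Ct/C0)`` against its own day-0 value; zero (below
    detection) concentrations are excluded. With ``breakpoint_day=None`` a
    single segment is fitted, otherwise two. Returns one row per DecayFit.
    """
    required = {"treatment", "replicate", "day", "gene", "copies_per_g_dw"}
    missing = required - set(abundance.columns)
    if missing:
        raise ValueError(f"abundance table missing columns: {sorted(missing)}")
    keys = ["treatment", "gene"] + (["replicate"] if per_replicate else [])
    rows = []
    work = abundance[abundance["gene"].isin(genes)]
    for key, sub in work.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        treatment, gene = key[0], key[1]
        series = (
            sub.groupby("day")["copies_per_g_dw"].mean().sort_index()
            if not per_replicate
            else sub.set_index("day")["copies_per_g_dw"].sort_index()
        )
        series = series[series > 0]
        if 0 not in series.index:
            raise ValueError(f"series {key} has no positive day-0 value for C0")
        c0 = series.loc[0]
        c0 = float(np.asarray(c0).mean())
        days = series.index.to_numpy(dtype=float)
        lrs = np.array([log_ratio(ct, c0) for ct in series.to_numpy(dtype=float)])
        if breakpoint_day is None:
            fits = [fit_linear_decay(days, lrs, gene=gene, treatment=treatment)]
        else:
            fits = list(
                fit_biphasic(days, lrs, breakpoint_day, gene=gene, treatment=treatment,
                             search_breakpoint=search_breakpoint)
            )
        for f in fits:
            row = {
                "treatment": treatment,
                "gene": gene,
                "segment": f.segment_label,
                "day_min": f.day_range[0],
                "day_max": f.day_range[1],
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "d_value": f.d_value,
                "n_points": f.n_points,
            }
            if per_replicate:
                row["replicate"] = key[2]
            rows.append(row)
    return pd.DataFrame(rows)
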
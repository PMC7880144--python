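"""Statistical comparisons for condition- and phase-wise ocular metrics.

One-way between-groups ANOVA with an eta-squared effect size
(SS_between / SS_total), pairwise two-sample t-tests (optionally paired,
optionally Holm-corrected), Welch's unequal-variance t-test, Pearson
correlation with a resampling alignment utility for differently-timed
series, and the signed rate-of-descent derivative (negative while
descending, positive in a climb).

Exact p-values are always reported; the significance level is the
caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, UndefinedCorrelationError, ValidationError

__all__ = [
    "ConditionData",
    "TestResult",
    "oneway_anova",
    "pairwise_ttests",
    "welch_ttest",
    "correlate",
    "align_series",
    "correlate_aligned",
    "rate_of_descent",
]


@dataclass
class ConditionData:
    """Per-condition (or per-phase) metric values, one value per
    participant or window."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


@dataclass
class TestResult:
    """A test statistic with degrees of freedom, p-value and optional
    effect size (a proportion of variance in [0, 1])."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float | None = None


def _as_groups(
    groups: Sequence[ConditionData] | Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> list[ConditionData]:
    if isinstance(groups, Mapping):
        return [ConditionData(str(k), np.asarray(v, float)) for k, v in groups.items()]
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, ConditionData):
            out.append(g)
        else:
            out.append(ConditionData(f"g{i}", np.asarray(g, float)))
    return out


def oneway_anova(groups) -> TestResult:
    """Classical one-way between-groups ANOVA.

    Effect size is eta-squared = SS_between / SS_total.  With zero
    within-group variance and distinct means the F statistic is unbounded:
    ``statistic`` is +inf, p is 0 and the effect size 1.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InsufficientDataError("ANOVA needs at least 2 groups")
    for g in gs:
        if len(g.values) < 2:
            raise InsufficientDataError(f"group {g.label!r} has fewer than 2 values")
    all_vals = np.concatenate([g.values for g in gs])
    grand = all_vals.mean()
    ss_between = sum(len(g.values) * (g.values.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g.values - g.values.mean()) ** 2).sum() for g in gs)
    ss_total = ss_between + ss_within
    k, n = len(gs), len(all_vals)
    df1, df2 = k - 1, n - k
    eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within == 0:
        if ss_between == 0:
            return TestResult(0.0, (df1, df2), 1.0, 0.0)
        return TestResult(float("inf"), (df1, df2), 0.0, 1.0)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, df2), p, float(eta_sq))


def pairwise_ttests(
    groups, paired: bool = False, correction: str | None = None
) -> pd.DataFrame:
    """Two-sample t-test for every unordered pair of groups.

    No multiple-comparison correction is applied by default;
    ``correction='holm'`` adds Holm-adjusted p-values.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise InsufficientDataError("need at least 2 groups")
    rows = []
    for a, b in combinations(gs, 2):
        if len(a.values) < 2 or len(b.values) < 2:
            raise InsufficientDataError("each group needs at least 2 values")
        if paired:
            if len(a.values) != len(b.values):
                raise ValidationError("paired test requires equal group sizes")
            res = sps.ttest_rel(a.values, b.values)
            df = len(a.values) - 1
        else:
            res = sps.ttest_ind(a.values, b.values)
            df = len(a.values) + len(b.values) - 2
        rows.append(
            {"a": a.label, "b": b.label, "t": float(res.statistic),
             "df": float(df), "p": float(res.pvalue)}
        )
    table = pd.DataFrame(rows)
    if correction == "holm":
        m = len(table)
        order = np.argsort(table["p"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        table["p_holm"] = adj
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    return table


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sample t-test with
    Welch-Satterthwaite degrees of freedom."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValidationError("series must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def align_series(
    t_x: Sequence[float],
    x: Sequence[float],
    t_y: Sequence[float],
    y: Sequence[float],
    grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample two differently-timed series onto a common grid by linear
    interpolation, restricted to the overlap of their spans.

    Returns ``(grid, x_resampled, y_resampled)``.  The default grid has the
    coarser of the two native resolutions.
    """
    t_x, x = np.asarray(t_x, float), np.asarray(x, float)
    t_y, y = np.asarray(t_y, float), np.asarray(y, float)
    lo = max(t_x[0], t_y[0])
    hi = min(t_x[-1], t_y[-1])
    if hi <= lo:
        raise ValidationError("series have no temporal overlap")
    if grid is None:
        step = max(np.median(np.diff(t_x)), np.median(np.diff(t_y)))
        grid = np.clip(np.arange(lo, hi + step / 2, step), lo, hi)
    else:
        grid = np.asarray(grid, float)
    return grid, np.interp(grid, t_x, x), np.interp(grid, t_y, y)


def correlate_aligned(t_x, x, t_y, y) -> tuple[float, float]:
    """Pearson correlation of two differently-timed series after resampling
    onto a common grid (e.g. fixation rate vs rate of descent)."""
    _, xr, yr = align_series(t_x, x, t_y, y)
    return correlate(xr, yr)


def rate_of_descent(t: Sequence[float], altitude: Sequence[float]) -> np.ndarray:
    """Signed vertical speed from an altitude trace by central difference:
    negative while descending, positive in a climb."""
    t = np.asarray(t, float)
    altitude = np.asarray(altitude, float)
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 samples")
    return np.gradient(altitude, t)
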
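"""Evolutionary rates through time by 1-Myr tree slicing.

Every branch carrying a rate annotation contributes that rate to each time
slice it crosses; the per-slice median summarizes the rate at that moment,
and a loess curve smooths the medians into a long-term trend.  The crossing
rule is half-open — a branch with parent age p and child age c crosses
slice t iff c <= t < p — so a branch ending exactly on a slice is not
double-counted with its child.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TimeTree, TreeValidationError

__all__ = [
    "RateTimeSeries",
    "LoessTrend",
    "slice_rates",
    "loess_trend",
    "rates_by_group",
    "series_to_frame",
]


@dataclass
class RateTimeSeries:
    """Per-slice multisets of branch rates and their medians.

    ``slice_times`` decrease in Ma (forward in time); ``medians`` is NaN
    where no branch crosses the slice.
    """

    slice_times: np.ndarray
    slice_rates: list
    medians: np.ndarray
    group: str = "all"

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.medians).sum())


@dataclass
class LoessTrend:
    span: float
    degree: int
    times: np.ndarray
    fitted: np.ndarray


def _branch_in_scope(node, scope) -> bool:
    if scope is None:
        return True
    if callable(scope):
        return bool(scope(node))
    tips = {lf.taxon.label for lf in node.leaf_iter()}
    return tips <= set(scope)


def slice_rates(tree: TimeTree, from_ma: float, to_ma: float, step: float = 1.0,
                scope=None, group: str = "all") -> RateTimeSeries:
    """Collate branch rates crossing each slice between two ages.

    ``scope`` restricts the branches: either a set of tip labels (a branch
    counts iff all its descendant tips are in the set, which keeps a clade
    plus its stem and drops e.g. outgroup branches) or a predicate on the
    branch's child node.
    """
    if not from_ma > to_ma:
        raise ValueError("from_ma must be older (larger) than to_ma")
    if not tree.has_rates:
        raise TreeValidationError("tree carries no branch-rate annotations")
    times = np.arange(from_ma, to_ma - 1e-9, -step)
    buckets = [[] for _ in times]
    for nd in tree.branches():
        rate = getattr(nd, "rate", None)
        if rate is None or not _branch_in_scope(nd, scope):
            continue
        p, c = nd.parent_node.age, nd.age
        crossing = (times >= c) & (times < p)
        for k in np.nonzero(crossing)[0]:
            buckets[k].append(rate)
    medians = np.array([np.median(b) if b else np.nan for b in buckets])
    return RateTimeSeries(times, [np.array(b) for b in buckets], medians, group=group)


# ---------------------------------------------------------------------------
# Loess trend
# ---------------------------------------------------------------------------

def _loess(x, y, span: float, degree: int, grid):
    """Local weighted polynomial regression with tricube weights.

    For each grid point the nearest ceil(span*n) observations define the
    neighbourhood; weights are tricube in scaled distance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    out = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        # weighted polynomial fit centred on the grid point
        X = np.vander(x[idx] - g, degree + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        out[i] = coef[0]
    return out


def loess_trend(series: RateTimeSeries, span: float = 0.75, degree: int = 2) -> LoessTrend:
    """Smooth the per-slice medians; fitted values returned on the slice grid."""
    ok = np.isfinite(series.medians)
    if ok.sum() < 5:
        raise ValueError("loess trend needs at least 5 defined medians")
    fitted = np.full(series.slice_times.size, np.nan)
    fitted[ok] = _loess(series.slice_times[ok], series.medians[ok], span, degree,
                        series.slice_times[ok])
    return LoessTrend(span=span, degree=degree, times=series.slice_times, fitted=fitted)


# ---------------------------------------------------------------------------
# Grouped series
# ---------------------------------------------------------------------------

def rates_by_group(tree: TimeTree, tip_groups: dict, groups, from_ma: float,
                   to_ma: float, step: float = 1.0) -> dict:
    """One rate series per group.

    A branch belongs to a group iff every descendant tip maps to that group
    (this includes the clade's stem branch); branches whose descendants span
    several groups, or include unassigned tips, belong to none.
    """
    series = {}
    for g in groups:
        members = {t for t, grp in tip_groups.items() if grp == g}
        if not members & set(tree.taxon_labels):
            warnings.warn(f"group {g!r} has no tips in the tree")
            series[g] = RateTimeSeries(
                np.arange(from_ma, to_ma - 1e-9, -step), [], np.array([]), group=g)
            series[g].slice_rates = [np.array([]) for _ in series[g].slice_times]
            series[g].medians = np.full(series[g].slice_times.size, np.nan)
            continue
        series[g] = slice_rates(tree, from_ma, to_ma, step, scope=members, group=g)
    return series


def series_to_frame(series_map, trends=None) -> pd.DataFrame:
    """Tidy export: group, slice_ma, n_branches, median, loess_fit."""
    rows = []
    for g, s in (series_map.items() if isinstance(series_map, dict)
                 else [(series_map.group, series_map)]):
        fit = trends[g].fitted if trends and g in trends else [np.nan] * len(s.slice_times)
        for t, bucket, med, f in zip(s.slice_times, s.slice_rates, s.medians, fit):
            rows.append(dict(group=g, slice_ma=t, n_branches=len(bucket),
                             median=med, loess_fit=f))
    return pd.DataFrame(rows)
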
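"""Before/after social-distancing reduction metrics.

The study window splits into a long "before" period and an "after"
period starting at the national social-distancing announcement
(defaults: 2019-01-01 .. 2020-03-15 before, 2020-03-16 .. 2020-04-27
after). Three views of the drop in mobility:

* group-level: ``100 * (mean_before - mean_after) / mean_before`` on the
  regional mean weekly index over all retained user-weeks of a period;
* user-level: the same formula per user on their per-period mean index
  ``M``, summarized by the median over "active" users (at least two
  resolved check-ins in both periods) together with the fraction of
  active users whose after-period index is exactly zero ("complete"
  reduction);
* seasonal: the user-level formula with the before window replaced by
  the identical calendar window one year earlier, controlling for
  seasonal travel.

A user whose before-period index is 0 while the after-period index is
positive has no finite percentage reduction; such users are reported as
null and excluded from medians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from geomobility.mobility import _attach_week, _events_frame

logger = logging.getLogger(__name__)

DEFAULT_BEFORE_START = date(2019, 1, 1)
DEFAULT_SPLIT = date(2020, 3, 16)
DEFAULT_AFTER_END = date(2020, 4, 27)


def _shift_year(d: date) -> date:
    try:
        return d.replace(year=d.year - 1)
    except ValueError:  # Feb 29
        return d.replace(year=d.year - 1, day=28)


@dataclass(frozen=True)
class PeriodSplit:
    """Before/after date intervals and the seasonal reference window."""

    before_start: date = DEFAULT_BEFORE_START
    split: date = DEFAULT_SPLIT
    after_end: date = DEFAULT_AFTER_END

    def __post_init__(self):
        if not (self.before_start < self.split <= self.after_end):
            raise ValueError("require before_start < split <= after_end")

    @property
    def seasonal_start(self) -> date:
        return _shift_year(self.split)

    @property
    def seasonal_end(self) -> date:
        return _shift_year(self.after_end)

    def period_of(self, d: date) -> str | None:
        if self.before_start <= d < self.split:
            return "before"
        if self.split <= d <= self.after_end:
            return "after"
        return None

    def in_seasonal(self, d: date) -> bool:
        return self.seasonal_start <= d <= self.seasonal_end


def group_reduction(before_mean: float, after_mean: float) -> float | None:
    """Percent drop ``100 * (before - after) / before``; None if before = 0.

    Negative when mobility rose.
    """
    if before_mean == 0:
        warnings.warn("group reduction undefined: before-period mean is 0")
        return None
    return 100.0 * (before_mean - after_mean) / before_mean


def _period_user_index(user_weeks: pd.DataFrame, mask) -> pd.Series:
    uw = user_weeks[mask]
    return uw.groupby("user_id")["weekly_index_km"].mean()


def _reductions_frame(
    events_df: pd.DataFrame,
    user_weeks: pd.DataFrame,
    before_days,
    after_days,
    min_checkins: int = 2,
) -> pd.DataFrame:
    """Per-user reductions between two arbitrary day-predicate windows.

    ``before_days`` / ``after_days`` are vectorized predicates over a
    Series of dates. Active users have >= ``min_checkins`` resolved
    check-ins in each window; a window with check-ins but no retained
    week contributes an index of 0 (no measurable travel).
    """
    days = events_df["day"]
    n_before = events_df[before_days(days)].groupby("user_id").size()
    n_after = events_df[after_days(days)].groupby("user_id").size()
    active = n_before[n_before >= min_checkins].index.intersection(
        n_after[n_after >= min_checkins].index
    )

    wk_days = pd.Series(user_weeks["week_start"])
    m_before = _period_user_index(user_weeks, before_days(wk_days).to_numpy())
    m_after = _period_user_index(user_weeks, after_days(wk_days).to_numpy())

    out = pd.DataFrame(index=active)
    out["M_before"] = m_before.reindex(active).fillna(0.0)
    out["M_after"] = m_after.reindex(active).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        red = 100.0 * (out["M_before"] - out["M_after"]) / out["M_before"]
    out["reduction_pct"] = red.where(out["M_before"] > 0, np.nan)
    out["complete"] = (out["M_before"] > 0) & (out["M_after"] == 0)
    out.index.name = "user_id"
    return out.reset_index()


def _summary(per_user: pd.DataFrame) -> dict:
    n_active = len(per_user)
    if n_active == 0:
        warnings.warn("no active users in both periods")
        return {"median_reduction_pct": None, "n_active": 0, "fraction_complete": None}
    return {
        "median_reduction_pct": float(per_user["reduction_pct"].median(skipna=True))
        if per_user["reduction_pct"].notna().any()
        else None,
        "n_active": n_active,
        "fraction_complete": float(per_user["complete"].mean()),
    }


def user_reductions(
    events,
    user_weeks: pd.DataFrame,
    split: PeriodSplit | None = None,
    min_checkins: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Per-user before/after reduction and the cohort summary.

    Returns ``(per_user, summary)`` where ``per_user`` has columns
    ``user_id, M_before, M_after, reduction_pct, complete`` over active
    users, and ``summary`` carries the median reduction, active-user
    count and complete-reduction fraction.
    """
    split = split or PeriodSplit()
    df = _attach_week(_events_frame(events))
    per_user = _reductions_frame(
        df,
        user_weeks,
        lambda d: (d >= split.before_start) & (d < split.split),
        lambda d: (d >= split.split) & (d <= split.after_end),
        min_checkins,
    )
    return per_user, _summary(per_user)


def seasonal_reductions(
    events,
    user_weeks: pd.DataFrame,
    split: PeriodSplit | None = None,
    min_checkins: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """User-level reduction versus the same calendar window one year back.

    Users with no check-ins in the seasonal reference window fail the
    activity filter and drop out of the summary.
    """
    split = split or PeriodSplit()
    per_user = _reductions_frame(
        _attach_week(_events_frame(events)),
        user_weeks,
        lambda d: (d >= split.seasonal_start) & (d <= split.seasonal_end),
        lambda d: (d >= split.split) & (d <= split.after_end),
        min_checkins,
    )
    return per_user, _summary(per_user)


def build_reduction_report(
    events,
    user_weeks: pd.DataFrame,
    assignment: dict,
    split: PeriodSplit | None = None,
    min_checkins: int = 2,
    include_national: bool = True,
    national_id: str = "ALL",
) -> pd.DataFrame:
    """Per-region reduction report (the shape of the study's main tables).

    Columns: ``region_id, mobility_before_km, mobility_after_km,
    group_reduction_pct, median_user_reduction_pct,
    median_seasonal_reduction_pct, n_active_users,
    fraction_complete_reduction, rank``. Group means average the retained
    user-week indices of a period. Ranks (1 = largest group reduction,
    ties broken by region_id) cover the regions only; the national row,
    aggregating every assigned user, carries no rank.
    """
    split = split or PeriodSplit()
    df = _attach_week(_events_frame(events))
    uw = user_weeks.copy()
    uw["region_id"] = uw["user_id"].map(assignment)
    uw = uw.dropna(subset=["region_id"])
    ev = df[df["user_id"].map(assignment).notna()]

    per_user, _ = user_reductions(ev, uw, split, min_checkins)
    per_user_seas, _ = seasonal_reductions(ev, uw, split, min_checkins)
    per_user["region_id"] = per_user["user_id"].map(assignment)
    per_user_seas["region_id"] = per_user_seas["user_id"].map(assignment)

    wk_period = pd.Series(uw["week_start"]).map(split.period_of)
    groups = [(rid, g) for rid, g in uw.groupby("region_id")]
    if include_national:
        groups.append((national_id, uw))

    rows = []
    for rid, g in groups:
        period = wk_period.loc[g.index]
        before = g.loc[period == "before", "weekly_index_km"]
        after = g.loc[period == "after", "weekly_index_km"]
        before_m = float(before.mean()) if len(before) else np.nan
        after_m = float(after.mean()) if len(after) else np.nan
        grp = (
            group_reduction(before_m, after_m)
            if np.isfinite(before_m) and np.isfinite(after_m) and before_m > 0
            else None
        )
        if rid == national_id and include_national:
            pu = per_user
            ps = per_user_seas
        else:
            pu = per_user[per_user["region_id"] == rid]
            ps = per_user_seas[per_user_seas["region_id"] == rid]
        s = _summary(pu)
        ss = _summary(ps) if len(ps) else {"median_reduction_pct": None}
        rows.append(
            {
                "region_id": rid,
                "mobility_before_km": before_m,
                "mobility_after_km": after_m,
                "group_reduction_pct": grp,
                "median_user_reduction_pct": s["median_reduction_pct"],
                "median_seasonal_reduction_pct": ss["median_reduction_pct"],
                "n_active_users": s["n_active"],
                "fraction_complete_reduction": s["fraction_complete"],
            }
        )
    report = pd.DataFrame(rows)
    return rank_regions(report, national_id=national_id if include_national else None)


def rank_regions(report: pd.DataFrame, national_id: str | None = None) -> pd.DataFrame:
    """Attach ranks: 1 = largest group reduction, ties by region_id.

    The national aggregate row (``national_id``) gets no rank.
    """
    report = report.copy()
    mask = report["region_id"] != national_id if national_id is not None else np.ones(len(report), bool)
    sub = report[mask].sort_values(
        ["group_reduction_pct", "region_id"], ascending=[False, True], kind="stable"
    )
    ranks = pd.Series(np.arange(1, len(sub) + 1), index=sub.index)
    report["rank"] = ranks.reindex(report.index)
    report["rank"] = report["rank"].astype("Int64")
    return report
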
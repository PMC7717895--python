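"""The social mobility index: weekly travel dispersion per user.

For each user and Monday-start week (UTC), the check-in coordinate
sequence ``C_1..C_n`` defines a weekly centroid (the "home" for that
week); the distance sequence ``D`` holds the geodesic distance in km of
each check-in to that centroid, and the weekly index is the population
standard deviation of ``D``. A user's overall index ``M`` is the mean of
their weekly indices over the ``N`` retained weeks. Sparse-data filters:
users with fewer than 3 resolved check-ins overall are dropped, as are
user-weeks with fewer than 3 check-ins; whole weeks whose total user or
record count falls below a one-sided 99.75% lower normal limit of the
weekly-count distribution are treated as collection failures and removed
from every aggregate.

The index reflects the area and regularity of travel rather than raw
distance traveled: a user posting from a single point all week scores
exactly 0 regardless of how often they post.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
from scipy import stats as sps

from geomobility.geodesy import distances_to_point_km, geodesic_km, spherical_centroid
logger = logging.getLogger(__name__)

MIN_WEEKLY_POINTS = 3
MIN_TOTAL_POINTS = 3
DATA_LOSS_LIMIT = 0.9975

# dispersions below one nanometre are float-cancellation residue from the
# centroid round-trip on identical points; snap them to an exact zero so
# "no travel" and "complete reduction" are exact, not approximate
_ZERO_STD_KM = 1e-12


def _pop_std(values: np.ndarray) -> float:
    s = float(np.std(values, ddof=0))
    return 0.0 if s < _ZERO_STD_KM else s


def week_of(timestamp: datetime) -> date:
    """Monday (UTC date) of the week containing ``timestamp``."""
    if timestamp.tzinfo is not None:
        timestamp = timestamp.astimezone(timezone.utc)
    d = timestamp.date()
    return d - timedelta(days=d.weekday())


def weekly_index(points) -> float:
    """Population standard deviation (km) of distances to the centroid.

    ``points`` is a sequence of ``(lat, lon)`` with at least
    ``MIN_WEEKLY_POINTS`` entries; order of points does not matter.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < MIN_WEEKLY_POINTS:
        raise ValueError(
            f"weekly index needs >= {MIN_WEEKLY_POINTS} points, got {pts.shape[0]}"
        )
    center = spherical_centroid(pts)
    d = distances_to_point_km(pts, center)
    return _pop_std(d)


@dataclass(frozen=True)
class UserWeekRecord:
    """One user's retained week: points, distance sequence and index."""

    user_id: str
    week_start: date
    points: tuple[tuple[float, float], ...]
    distances_km: tuple[float, ...]
    weekly_index_km: float

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class UserIndexSeries:
    """A user's retained weekly indices and their mean M."""

    user_id: str
    weekly: dict  # week_start -> weekly_index_km
    all_time_centroid: tuple[float, float]

    @property
    def n_weeks(self) -> int:
        return len(self.weekly)

    @property
    def M(self) -> float:
        return float(np.mean(list(self.weekly.values())))


def _events_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        rows = [(e.user_id, e.timestamp, e.lat, e.lon) for e in events]
        df = pd.DataFrame(rows, columns=["user_id", "timestamp", "lat", "lon"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def _attach_week(df: pd.DataFrame) -> pd.DataFrame:
    ts = df["timestamp"].dt.tz_convert("UTC")
    df["week_start"] = (ts - pd.to_timedelta(ts.dt.weekday, unit="D")).dt.date
    df["day"] = ts.dt.date
    return df


def _group_centroids(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Spherical centroid per group, vectorized via 3-D unit vectors."""
    phi = np.radians(df["lat"].to_numpy())
    lam = np.radians(df["lon"].to_numpy())
    tmp = df[keys].copy()
    tmp["x"] = np.cos(phi) * np.cos(lam)
    tmp["y"] = np.cos(phi) * np.sin(lam)
    tmp["z"] = np.sin(phi)
    m = tmp.groupby(keys, sort=False)[["x", "y", "z"]].mean()
    norm = np.sqrt((m**2).sum(axis=1))
    cent = pd.DataFrame(index=m.index)
    cent["c_lat"] = np.degrees(np.arcsin(m["z"] / norm))
    cent["c_lon"] = np.degrees(np.arctan2(m["y"], m["x"]))
    return cent.reset_index()


@dataclass
class UserWeekResult:
    """Output of :func:`build_user_weeks`.

    ``user_weeks``: one row per retained (user, week) with columns
    ``user_id, week_start, n, weekly_index_km``.
    ``users``: one row per retained user with ``user_id, n_weeks, M_km,
    centroid_lat, centroid_lon`` (centroid over every resolved event of
    the user, including events in dropped weeks).
    ``weekly_totals``: pre-filter per-week ``n_users, n_records`` counts
    over all resolved events, used for data-loss screening.
    """

    user_weeks: pd.DataFrame
    users: pd.DataFrame
    weekly_totals: pd.DataFrame

    def user_series(self, user_id: str) -> UserIndexSeries:
        uw = self.user_weeks[self.user_weeks["user_id"] == user_id]
        urow = self.users.set_index("user_id").loc[user_id]
        return UserIndexSeries(
            user_id=user_id,
            weekly=dict(zip(uw["week_start"], uw["weekly_index_km"])),
            all_time_centroid=(float(urow["centroid_lat"]), float(urow["centroid_lon"])),
        )


def build_user_weeks(
    events,
    min_total: int = MIN_TOTAL_POINTS,
    min_weekly: int = MIN_WEEKLY_POINTS,
    exclude_weeks: set | None = None,
) -> UserWeekResult:
    """Compute retained weekly indices and per-user summaries.

    ``events`` is an iterable of :class:`~geomobility.ingest.GeoEvent` or a
    DataFrame with columns ``user_id, timestamp, lat, lon``. Users with
    fewer than ``min_total`` events overall are dropped entirely;
    user-weeks with fewer than ``min_weekly`` events are dropped. Weeks in
    ``exclude_weeks`` (data-loss screening) are removed before filtering.
    """
    df = _attach_week(_events_frame(events))
    if df.empty:
        empty_uw = pd.DataFrame(columns=["user_id", "week_start", "n", "weekly_index_km"])
        empty_u = pd.DataFrame(columns=["user_id", "n_weeks", "M_km", "centroid_lat", "centroid_lon"])
        empty_t = pd.DataFrame(columns=["week_start", "n_users", "n_records"])
        return UserWeekResult(empty_uw, empty_u, empty_t)

    weekly_totals = (
        df.groupby("week_start")
        .agg(n_users=("user_id", "nunique"), n_records=("user_id", "size"))
        .reset_index()
    )

    if exclude_weeks:
        df = df[~df["week_start"].isin(set(exclude_weeks))]

    total = df.groupby("user_id")["lat"].transform("size")
    df = df[total >= min_total]

    # all-time centroid over every remaining event of each retained user
    user_cent = _group_centroids(df, ["user_id"]).rename(
        columns={"c_lat": "centroid_lat", "c_lon": "centroid_lon"}
    )

    wk_size = df.groupby(["user_id", "week_start"])["lat"].transform("size")
    wk = df[wk_size >= min_weekly].copy()

    if wk.empty:
        user_weeks = pd.DataFrame(columns=["user_id", "week_start", "n", "weekly_index_km"])
    else:
        cent = _group_centroids(wk, ["user_id", "week_start"])
        wk = wk.merge(cent, on=["user_id", "week_start"], how="left")
        d = geodesic_km(
            (wk["lat"].to_numpy(), wk["lon"].to_numpy()),
            (wk["c_lat"].to_numpy(), wk["c_lon"].to_numpy()),
        )
        wk["dist_km"] = d
        user_weeks = (
            wk.groupby(["user_id", "week_start"])["dist_km"]
            .agg(n="size", weekly_index_km=lambda s: _pop_std(s.to_numpy()))
            .reset_index()
        )

    users = (
        user_weeks.groupby("user_id")
        .agg(n_weeks=("week_start", "size"), M_km=("weekly_index_km", "mean"))
        .reset_index()
        .merge(user_cent, on="user_id", how="left")
    )
    logger.info(
        "retained %d users, %d user-weeks", len(users), len(user_weeks)
    )
    return UserWeekResult(user_weeks=user_weeks, users=users, weekly_totals=weekly_totals)


def detect_data_loss_weeks(
    weekly_totals: pd.DataFrame, limit: float = DATA_LOSS_LIMIT
) -> set:
    """Weeks whose user OR record count falls below the lower normal limit.

    The limit is one-sided: ``mean - z * sd`` with ``z`` the normal
    quantile for ``limit`` (z ~ 2.807 at 99.75%), applied independently to
    the weekly user-count and record-count series. Needs at least 4 weeks;
    otherwise returns the empty set with a warning.
    """
    if len(weekly_totals) < 4:
        warnings.warn("too few weeks to estimate data-loss limits; no exclusions")
        return set()
    z = float(sps.norm.ppf(limit))
    excluded: set = set()
    for col in ("n_users", "n_records"):
        x = weekly_totals[col].to_numpy(dtype=float)
        lo = x.mean() - z * x.std(ddof=1)
        mask = x < lo
        excluded.update(weekly_totals["week_start"].to_numpy()[mask])
    if excluded:
        logger.info("data-loss screening excluded weeks: %s", sorted(excluded))
    return excluded


def aggregate_region_week(
    user_weeks: pd.DataFrame, assignment: dict
) -> pd.DataFrame:
    """Regional weekly mean/variance/count of user weekly indices.

    ``assignment`` maps user_id to region_id; unassigned users are
    skipped. Variance is the population variance of that week's user
    indices. Returns columns ``region_id, week_start, mean_km, variance,
    n_users``; region-weeks with no users are simply absent.
    """
    uw = user_weeks.copy()
    uw["region_id"] = uw["user_id"].map(assignment)
    uw = uw.dropna(subset=["region_id"])
    out = (
        uw.groupby(["region_id", "week_start"])["weekly_index_km"]
        .agg(
            mean_km="mean",
            variance=lambda s: float(np.var(s.to_numpy(), ddof=0)),
            n_users="size",
        )
        .reset_index()
    )
    return out


def daily_moving_average(
    events,
    window: int = 7,
    min_points: int = MIN_WEEKLY_POINTS,
    assignment: dict | None = None,
) -> pd.DataFrame:
    """Daily mobility series: trailing ``window``-day per-user indices.

    For each calendar day ``t`` and user, the dispersion index (population
    std of distances to the window centroid) is computed over the user's
    points in the trailing window ``[t - window + 1, t]`` when it holds at
    least ``min_points`` points; the daily value is the mean of these
    per-user indices. The first ``window - 1`` days of the data range are
    not emitted (incomplete window). With ``assignment`` the series is
    computed per region; otherwise one pooled series is returned with
    ``region_id = "all"``.

    Returns columns ``region_id, day, index_km, n_users``.
    """
    df = _attach_week(_events_frame(events))
    if df.empty:
        return pd.DataFrame(columns=["region_id", "day", "index_km", "n_users"])
    if assignment is not None:
        df["region_id"] = df["user_id"].map(assignment)
        df = df.dropna(subset=["region_id"])
    else:
        df["region_id"] = "all"

    days = pd.date_range(df["day"].min(), df["day"].max(), freq="D").date
    df = df.sort_values("day", kind="stable")
    day_arr = np.array(df["day"])
    rows = []
    for t in days[window - 1:]:
        lo = t - timedelta(days=window - 1)
        sel = df[(day_arr >= lo) & (day_arr <= t)]
        if sel.empty:
            continue
        counts = sel.groupby(["region_id", "user_id"])["lat"].transform("size")
        sel = sel[counts >= min_points]
        if sel.empty:
            continue
        cent = _group_centroids(sel, ["region_id", "user_id"])
        sel = sel.merge(cent, on=["region_id", "user_id"], how="left")
        d = geodesic_km(
            (sel["lat"].to_numpy(), sel["lon"].to_numpy()),
            (sel["c_lat"].to_numpy(), sel["c_lon"].to_numpy()),
        )
        sel = sel.assign(dist_km=d)
        per_user = (
            sel.groupby(["region_id", "user_id"])["dist_km"]
            .agg(lambda s: _pop_std(s.to_numpy()))
        )
        agg = per_user.groupby("region_id").agg(["mean", "size"])
        for region_id, (mean_v, n_u) in agg.iterrows():
            rows.append((region_id, t, float(mean_v), int(n_u)))
    return pd.DataFrame(rows, columns=["region_id", "day", "index_km", "n_users"])


def log1p_summary(indices) -> dict:
    """Five-number summary of ``log(1 + x)`` over user indices.

    The user-index distribution is long-tailed with many zeros, so box
    plots are drawn on the log1p scale. Whiskers follow the Tukey
    1.5 * IQR convention, clipped to the observed range.
    """
    x = np.log1p(np.asarray(indices, dtype=float))
    if np.any(x < 0):
        raise ValueError("indices must be >= 0")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo = float(x[x >= q1 - 1.5 * iqr].min())
    hi = float(x[x <= q3 + 1.5 * iqr].max())
    return {
        "whisker_low": lo,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_high": hi,
    }
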
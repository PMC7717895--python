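"""Offline change-point detection and related time-series summaries.

Change points in the daily moving-average mobility series are found by
binary segmentation with an L2 cost: a segment's cost is its sum of
squared deviations from the segment mean, and a split is accepted while
the cost reduction exceeds a penalty. The default penalty is BIC-style,
``sigma2 * log(T)`` with ``sigma2`` a robust noise estimate from first
differences, and segments are at least 7 days long so week-scale
periodicity is not chased. All three knobs (penalty, minimum segment
length, maximum number of change points) are exposed. The procedure is
deterministic: no randomness enters detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ChangePointResult:
    """Detected change points for one series.

    ``changepoints`` are 0-based indices of the first sample of each new
    segment, strictly increasing. ``dates``, when index labels were
    supplied, carries the corresponding labels.
    """

    series_id: str
    changepoints: list[int]
    dates: list = field(default_factory=list)
    penalty: float = 0.0
    min_segment: int = 7


def largest_drop_week(weekly: pd.DataFrame | pd.Series):
    """Week with the largest week-over-week decrease in mean index.

    Accepts a Series indexed by week_start or a frame with columns
    ``week_start, mean_km``. Returns the later week of the maximizing
    pair; ties go to the earliest such week. On a monotone increasing
    series this is the week with the smallest increase (the maximal drop
    is negative).
    """
    if isinstance(weekly, pd.DataFrame):
        s = weekly.sort_values("week_start").set_index("week_start")["mean_km"]
    else:
        s = weekly.sort_index()
    if len(s) < 2:
        raise ValueError("need at least 2 weeks to find a drop")
    drops = s.shift(1) - s  # positive = decrease into this week
    drops = drops.iloc[1:]
    return drops.index[int(np.argmax(drops.to_numpy()))]


def _segment_cost(prefix: np.ndarray, prefix_sq: np.ndarray, a: int, b: int) -> float:
    """L2 cost of samples [a, b): SSE around the segment mean, O(1)."""
    n = b - a
    s = prefix[b] - prefix[a]
    sq = prefix_sq[b] - prefix_sq[a]
    return sq - s * s / n


def _best_split(prefix, prefix_sq, a, b, min_seg):
    best_gain, best_t = -np.inf, None
    whole = _segment_cost(prefix, prefix_sq, a, b)
    for t in range(a + min_seg, b - min_seg + 1):
        gain = whole - _segment_cost(prefix, prefix_sq, a, t) - _segment_cost(prefix, prefix_sq, t, b)
        if gain > best_gain:
            best_gain, best_t = gain, t
    return best_gain, best_t


def detect_changepoints(
    series,
    penalty: float | str = "bic",
    min_segment: int = 7,
    max_changepoints: int | None = None,
    series_id: str = "series",
) -> ChangePointResult:
    """Binary segmentation with L2 cost and penalized split acceptance.

    ``series`` is a 1-D array-like or a Series (its index labels are
    carried into ``dates``). ``penalty="bic"`` uses
    ``sigma2 * log(T)`` with ``sigma2 = median(|diff|)^2 / (2 * 0.6745^2)``,
    a robust first-difference noise estimate; pass a float to override.
    Splits are accepted greedily, largest cost reduction first, while the
    reduction exceeds the penalty. A series shorter than
    ``2 * min_segment`` yields no change points.
    """
    labels = None
    if isinstance(series, pd.Series):
        labels = series.index
        x = series.to_numpy(dtype=float)
    else:
        x = np.asarray(series, dtype=float)
    T = len(x)
    if penalty == "bic":
        if T >= 2:
            mad = np.median(np.abs(np.diff(x)))
            sigma2 = (mad / (np.sqrt(2.0) * 0.6745)) ** 2
            if sigma2 == 0:
                sigma2 = 1e-12  # noiseless series: any real step dwarfs this
            pen = sigma2 * np.log(T)
        else:
            pen = np.inf
    else:
        pen = float(penalty)

    result = ChangePointResult(series_id, [], [], penalty=pen, min_segment=min_segment)
    if T < 2 * min_segment:
        return result

    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(x * x)])

    # candidate heap: (gain, split, a, b), re-evaluated greedily
    segments = [(0, T)]
    cps: list[int] = []
    while True:
        if max_changepoints is not None and len(cps) >= max_changepoints:
            break
        best = (-np.inf, None, None)
        for (a, b) in segments:
            if b - a < 2 * min_segment:
                continue
            gain, t = _best_split(prefix, prefix_sq, a, b, min_segment)
            if t is not None and gain > best[0]:
                best = (gain, t, (a, b))
        gain, t, seg = best
        if t is None or gain <= pen:
            break
        a, b = seg
        segments.remove(seg)
        segments.extend([(a, t), (t, b)])
        cps.append(t)
    cps.sort()
    result.changepoints = cps
    if labels is not None:
        result.dates = [labels[i] for i in cps]
    return result


def changepoint_window_fraction(results, windows) -> float | None:
    """Percent of all detected change points inside their series' window.

    ``results`` maps series_id to :class:`ChangePointResult` (or is an
    iterable of results); ``windows`` maps series_id to an inclusive
    ``(start, end)`` pair comparable with the result's date labels.
    Returns None when no change points were detected anywhere.
    """
    if isinstance(results, dict):
        items = results.items()
    else:
        items = [(r.series_id, r) for r in results]
    total = inside = 0
    for sid, res in items:
        start, end = windows[sid]
        for d in res.dates:
            total += 1
            if start <= d <= end:
                inside += 1
    if total == 0:
        return None
    return 100.0 * inside / total


def stationarity_score(series, cutoff) -> tuple[float, float, bool] | None:
    """Compare volatility before a cutoff with the full series.

    The score of a segment is the variance of its first differences
    divided by the square of its mean — a scale-free volatility measure
    (a named stationarity test statistic is deliberately not used; this
    substitute is documented in the methods note). Returns
    ``(score_before, score_full, more_stationary_before)`` or None when
    fewer than 14 samples precede the cutoff. Constant series score 0.
    """
    if isinstance(series, pd.DataFrame):
        series = series.set_index("day")["index_km"]
    s = series.sort_index()
    before = s[s.index < cutoff]
    if len(before) < 14:
        return None

    def score(seg: pd.Series) -> float:
        x = seg.to_numpy(dtype=float)
        m = x.mean()
        if m == 0:
            return float(np.var(np.diff(x), ddof=0))
        return float(np.var(np.diff(x), ddof=0) / (m * m))

    sb, sf = score(before), score(s)
    return sb, sf, bool(sb < sf)
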
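"""Correlation analyses: infection rate vs regional covariates and policies.

Daily Pearson correlations are computed across regions between the daily
infection rate (new confirmed cases divided by population) and a static
regional covariate (state size, population density, unemployment, ...)
or the mobility index. The policy analysis correlates cumulative cases
at a reference date with the age of each policy (days between the
reference date and the policy release date), where regions that never
announced the policy receive a large negative sentinel (-1000 by
default) so their absence itself carries signal.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
from scipy import stats as sps

POLICY_MISSING_SENTINEL = -1000.0


def daily_infection_rate(cases: pd.DataFrame, population: pd.Series) -> pd.DataFrame:
    """Per region-day infection rate = new_cases / population.

    ``cases`` has columns ``region_id, date, new_cases``; ``population``
    is indexed by region_id with positive values. Negative case counts
    are an input error.
    """
    if (cases["new_cases"] < 0).any():
        raise ValueError("negative new_cases")
    if (population <= 0).any():
        raise ValueError("populations must be positive")
    out = cases.copy()
    out["rate"] = out["new_cases"].to_numpy(dtype=float) / out["region_id"].map(population).to_numpy(dtype=float)
    return out[["region_id", "date", "rate"]]


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 3:
        return None
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def daily_correlation(rates: pd.DataFrame, factor: pd.Series) -> pd.Series:
    """Pearson r per day between regional rates and a static covariate.

    ``rates`` has columns ``region_id, date, rate``; ``factor`` is
    indexed by region_id. Pairwise-complete: regions missing the
    covariate are dropped per day. Days with fewer than 3 paired regions
    or a zero-variance vector yield NaN.
    """
    out = {}
    for day, g in rates.groupby("date"):
        x = g["rate"].to_numpy(dtype=float)
        y = g["region_id"].map(factor).to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        r = _pearson(x[ok], y[ok])
        out[day] = np.nan if r is None else r
    return pd.Series(out).sort_index()


def policy_date_correlation(
    cumulative_cases: pd.Series,
    policy_dates: pd.DataFrame,
    reference_date: date,
    sentinel: float = POLICY_MISSING_SENTINEL,
) -> pd.DataFrame:
    """Pearson r and two-sided p per policy type against cumulative cases.

    ``cumulative_cases`` is indexed by region_id (cases at
    ``reference_date``); ``policy_dates`` has columns ``region_id,
    policy_type, date`` where a missing/NaT date means the region never
    announced that policy and is mapped to ``sentinel`` days. The
    predictor is ``(reference_date - release_date).days``. p-values use
    the standard two-sided t approximation for Pearson r. Policy types
    with zero predictor variance or fewer than 3 regions yield NaN.
    """
    rows = []
    for ptype, g in policy_dates.groupby("policy_type"):
        regions = g["region_id"]
        days = []
        for d in g["date"]:
            if d is None or (isinstance(d, float) and np.isnan(d)) or pd.isna(d):
                days.append(sentinel)
            else:
                if isinstance(d, pd.Timestamp):
                    d = d.date()
                days.append(float((reference_date - d).days))
        x = np.asarray(days, dtype=float)
        y = regions.map(cumulative_cases).to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            rows.append((ptype, np.nan, np.nan))
            continue
        r, p = sps.pearsonr(x, y)
        rows.append((ptype, float(r), float(p)))
    return pd.DataFrame(rows, columns=["policy_type", "r", "p"]).sort_values(
        "r", ascending=False, ignore_index=True
    )
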
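"""Per-interval climate covariates from daily weather and the ONI series.

Each trapping interval (a winter, October through April, or a summer, May
through September) aggregates the daily records that fall in its window:
mean temperature, coefficients of variation of temperature and rainfall
(sample SD / mean, zero-rain days included), total rainfall, each also with
a one-season lag, plus the mean Oceanic Nino Index over the window.
Covariates are z-transformed before entering design matrices, so slope
estimates read as effect per SD of covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calendar import OccasionCalendar

RAW_COLUMNS = [
    "temp_avg",
    "temp_cv",
    "temp_cv_onelag",
    "rain_sum",
    "rain_sum_onelag",
    "rain_cv",
    "rain_cv_onelag",
]


def _cv(x: np.ndarray) -> float:
    m = x.mean()
    if m == 0:
        raise ValueError("zero-mean series has undefined CV")
    return float(x.std(ddof=1) / abs(m))


def seasonal_aggregate(
    daily: pd.DataFrame,
    calendar: OccasionCalendar,
    monthly: bool = False,
) -> pd.DataFrame:
    """Aggregate daily weather into the per-interval covariate table.

    ``daily`` needs columns ``date`` (parseable), ``tavg`` (deg C) and
    ``prcp`` (cm, nonnegative).  Returns one row per interval (index 1-based)
    with the raw covariates of :data:`RAW_COLUMNS`; one-lag columns are exact
    shifts of their parents, missing (NaN) for the first interval.  With
    ``monthly=True`` CVs are computed over monthly aggregates instead of
    daily values.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in daily weather")
    if (df["prcp"] < 0).any():
        raise ValueError("negative precipitation")
    df["month"] = df["date"].dt.to_period("M")

    rows = []
    for t in range(1, calendar.n_intervals + 1):
        start, end = calendar.interval_window(t)
        sub = df[(df["month"] >= start) & (df["month"] <= end)]
        if sub.empty:
            raise ValueError(f"interval {t} ({start}..{end}) has no weather records")
        if monthly:
            grp = sub.groupby("month")
            tvals = grp["tavg"].mean().to_numpy()
            rvals = grp["prcp"].sum().to_numpy()
        else:
            tvals = sub["tavg"].to_numpy()
            rvals = sub["prcp"].to_numpy()
        rows.append(
            {
                "interval": t,
                "season": calendar.interval_seasons[t - 1],
                "temp_avg": float(tvals.mean()),
                "temp_cv": _cv(tvals),
                "rain_sum": float(sub["prcp"].sum()),
                "rain_cv": _cv(rvals) if rvals.mean() > 0 else 0.0,
            }
        )
    out = pd.DataFrame(rows).set_index("interval")
    for col in ("temp_cv", "rain_sum", "rain_cv"):
        out[f"{col}_onelag"] = out[col].shift(1)
    return out[["season"] + RAW_COLUMNS]


def z_transform(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Z-score numeric columns over their non-missing entries (sample SD)."""
    out = table.copy()
    cols = columns or [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    for c in cols:
        x = out[c]
        if x.notna().sum() < 2:
            raise ValueError(f"column {c!r} needs >= 2 non-missing values")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"column {c!r} has zero variance")
        out[c] = (x - x.mean()) / sd
    return out


def oni_episodes(series: pd.Series, threshold: float = 0.5, run: int = 5) -> pd.Series:
    """Classify the running 3-month ONI into ENSO episodes.

    ``series`` is indexed by the center month of each 3-month mean and must
    be contiguous.  A month belongs to an El Nino episode when it sits in a
    run of at least ``run`` consecutive values >= +threshold (inclusive, the
    NOAA convention); La Nina symmetric at <= -threshold; else neutral.
    """
    idx = pd.PeriodIndex(series.index, freq="M")
    if len(idx) > 1 and any((b - a).n != 1 for a, b in zip(idx[:-1], idx[1:])):
        raise ValueError("ONI series has gaps")
    vals = series.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("ONI series has missing values")
    labels = np.array(["neutral"] * len(vals), dtype=object)
    for sign, name in ((1, "elnino"), (-1, "lanina")):
        qual = sign * vals >= threshold
        start = 0
        for i in range(len(qual) + 1):
            if i == len(qual) or not qual[i]:
                if i - start >= run:
                    labels[start:i] = name
                start = i + 1
    return pd.Series(labels, index=idx, name="episode")


def oni_interval_covariate(
    series: pd.Series, calendar: OccasionCalendar
) -> pd.DataFrame:
    """Per-interval ONI covariate: mean of the 3-month values whose center
    month overlaps the interval window, plus the dominant episode label."""
    idx = pd.PeriodIndex(series.index, freq="M")
    series = pd.Series(series.to_numpy(dtype=float), index=idx)
    episodes = oni_episodes(series)
    rows = []
    for t in range(1, calendar.n_intervals + 1):
        start, end = calendar.interval_window(t)
        window = series[(idx >= start) & (idx <= end)]
        if window.empty:
            raise ValueError(f"no ONI values overlap interval {t}")
        ep = episodes[(idx >= start) & (idx <= end)]
        dominant = ep.mode().iloc[0]
        rows.append({"interval": t, "oni": float(window.mean()), "episode": dominant})
    return pd.DataFrame(rows).set_index("interval")
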
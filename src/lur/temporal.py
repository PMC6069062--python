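"""Temporal adjustment of asynchronous weekly measurements.

Weekly site measurements taken in different calendar weeks are made
comparable by subtracting a correction factor derived from a continuously
operating reference station: the difference between the reference mean over
the measurement week and its seasonal mean.  Daily reference values are the
working resolution; a completeness rule governs which days are averaged
directly and which are neighbour-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AllMissingError, RankDeficientError, SeasonWindowError

logger = logging.getLogger(__name__)

#: Fraction of hourly values that must be *exceeded* for a day to be averaged
#: directly (strictly more than 25% of 24 hours, i.e. at least 7).
MIN_HOURLY_FRACTION = 0.25


@dataclass(frozen=True)
class SeasonWindow:
    """A labelled, inclusive date range."""

    label: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.end < self.start:
            raise SeasonWindowError(f"season {self.label!r}: end precedes start")

    def contains(self, start: pd.Timestamp, end: pd.Timestamp) -> bool:
        return self.start <= pd.Timestamp(start) and pd.Timestamp(end) <= self.end


@dataclass(frozen=True)
class GapFillModel:
    """Linear model predicting daily NO2 from daily PM10 and solar radiation."""

    intercept: float
    pm10_coef: float
    solar_coef: float
    fit_correlation: float

    def predict(self, pm10: np.ndarray | float, solar: np.ndarray | float) -> np.ndarray:
        return self.intercept + self.pm10_coef * np.asarray(pm10) + self.solar_coef * np.asarray(solar)


#: Published reference-station preset (intercept, PM10 coefficient, solar
#: coefficient, training correlation); specific to one station, shipped for
#: reproduction runs only.
PAPER_GAP_FILL = GapFillModel(intercept=17.35, pm10_coef=1.0, solar_coef=-0.07, fit_correlation=0.82)


@dataclass
class AdjustedConcentration:
    site_id: str
    pollutant: str
    season: str
    value: float
    n_weeks_averaged: int
    clamped: bool


def daily_from_hourly(
    hourly: pd.Series,
    min_fraction: float = MIN_HOURLY_FRACTION,
    fill_gaps: bool = True,
) -> pd.Series:
    """Collapse an hourly series to daily means under a completeness rule.

    Days where the available fraction of the 24 hourly slots strictly exceeds
    ``min_fraction`` are averaged directly.  Other days are set to the mean of
    the nearest previous and next directly-averaged daily values (one-sided at
    the ends of the series) when ``fill_gaps`` is true, else left as NaN.
    """
    hourly = hourly.sort_index()
    if hourly.notna().sum() == 0:
        raise AllMissingError("hourly series contains no observed values")
    days = hourly.index.normalize()
    grouped = hourly.groupby(days)
    counts = grouped.apply(lambda s: s.notna().sum())
    means = grouped.mean()
    full_index = pd.date_range(counts.index.min(), counts.index.max(), freq="D")
    counts = counts.reindex(full_index, fill_value=0)
    means = means.reindex(full_index)
    good = counts > min_fraction * 24
    daily = means.where(good)
    if not fill_gaps:
        return daily
    if not good.any():
        raise AllMissingError("no day satisfies the hourly completeness rule")
    prev = daily.ffill()
    nxt = daily.bfill()
    filled = (prev + nxt) / 2.0
    filled = filled.where(prev.notna() | nxt.notna())
    filled[prev.isna()] = nxt[prev.isna()]
    filled[nxt.isna()] = prev[nxt.isna()]
    return filled


def estimate_pm25(daily_pm10: pd.Series) -> pd.Series:
    """Daily PM2.5 estimated as 50% of the daily PM10 concentration."""
    return daily_pm10 * 0.5


def fit_gap_fill(
    daily_no2: pd.Series,
    daily_pm10: pd.Series,
    daily_solar: pd.Series,
    min_overlap: int = 30,
) -> GapFillModel:
    """OLS of daily NO2 on daily PM10 and solar radiation over their overlap."""
    df = pd.DataFrame({"no2": daily_no2, "pm10": daily_pm10, "solar": daily_solar}).dropna()
    if len(df) < min_overlap:
        raise AllMissingError(
            f"gap-fill training overlap has {len(df)} days; at least {min_overlap} required"
        )
    X = np.column_stack([np.ones(len(df)), df["pm10"].to_numpy(), df["solar"].to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError("gap-fill design is rank deficient (constant regressor)")
    res = sm.OLS(df["no2"].to_numpy(), X).fit()
    fitted = res.predict(X)
    r = float(np.corrcoef(fitted, df["no2"].to_numpy())[0, 1])
    return GapFillModel(
        intercept=float(res.params[0]),
        pm10_coef=float(res.params[1]),
        solar_coef=float(res.params[2]),
        fit_correlation=r,
    )


def reference_daily(
    reference: pd.DataFrame,
    pollutant: str,
    gap_fill: GapFillModel | str | None = "fit",
    min_fraction: float = MIN_HOURLY_FRACTION,
) -> pd.Series:
    """Daily reference series for a pollutant from the hourly station record.

    ``pollutant`` is ``"no2"`` or ``"pm25"``.  PM2.5 is derived from daily
    PM10.  NO2 days that fail the completeness rule (e.g. after the station
    stopped reporting NO2) are filled from a gap-fill model: ``"fit"`` trains
    one on the overlap, ``"paper"`` uses the published preset, or pass a
    :class:`GapFillModel` directly.
    """
    pm10_daily = daily_from_hourly(reference["pm10"], min_fraction)
    if pollutant == "pm25":
        return estimate_pm25(pm10_daily)
    if pollutant != "no2":
        raise ValueError(f"unknown pollutant {pollutant!r}")
    no2_daily = daily_from_hourly(reference["no2"], min_fraction, fill_gaps=False)
    no2_daily = no2_daily.reindex(pm10_daily.index)
    missing = no2_daily.isna()
    if not missing.any():
        return no2_daily
    solar_daily = daily_from_hourly(reference["solar"], min_fraction)
    if gap_fill == "fit" or gap_fill is None:
        model = fit_gap_fill(no2_daily, pm10_daily, solar_daily)
    elif gap_fill == "paper":
        model = PAPER_GAP_FILL
    else:
        model = gap_fill
    no2_daily[missing] = model.predict(pm10_daily[missing], solar_daily[missing])
    return no2_daily


def correction_factor(
    ref_daily: pd.Series, start: pd.Timestamp, end: pd.Timestamp, window: SeasonWindow
) -> float:
    """Reference mean over [start, end] minus reference mean over the season."""
    week = ref_daily.loc[pd.Timestamp(start) : pd.Timestamp(end)]
    season = ref_daily.loc[window.start : window.end]
    if week.dropna().empty or season.dropna().empty:
        raise SeasonWindowError("reference series does not cover the requested period")
    return float(week.mean() - season.mean())


def adjust_one(
    value: float,
    start: pd.Timestamp,
    end: pd.Timestamp,
    ref_daily: pd.Series,
    window: SeasonWindow,
) -> tuple[float, float, bool]:
    """Adjust one measurement; returns (adjusted, correction factor, clamped)."""
    if not window.contains(start, end):
        raise SeasonWindowError(
            f"measurement week {pd.Timestamp(start).date()}..{pd.Timestamp(end).date()} "
            f"lies outside season {window.label!r}"
        )
    cf = correction_factor(ref_daily, start, end, window)
    adjusted = value - cf
    clamped = adjusted < 0
    if clamped:
        adjusted = 0.0
    return adjusted, cf, clamped


def adjust_records(
    records: pd.DataFrame,
    ref_daily: pd.Series,
    windows: Mapping[str, SeasonWindow],
) -> pd.DataFrame:
    """Vectorised :func:`adjust_one` over a measurement table.

    ``records`` needs columns ``site_id, pollutant, season, start_date,
    end_date, value_ugm3``.  Returns the table with ``adjusted, correction,
    clamped`` columns appended.
    """
    out = records.copy()
    adjusted = np.empty(len(out))
    correction = np.empty(len(out))
    clamped = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        window = windows[row.season]
        adjusted[i], correction[i], clamped[i] = adjust_one(
            row.value_ugm3, pd.Timestamp(row.start_date), pd.Timestamp(row.end_date), ref_daily, window
        )
    out["adjusted"] = adjusted
    out["correction"] = correction
    out["clamped"] = clamped
    return out


def seasonal_means(adjusted: pd.DataFrame, seasons: Sequence[str] = ("warm", "cold")) -> pd.DataFrame:
    """Per-site seasonal means plus an annual mean.

    Repeated measurements within a season are averaged first; the annual mean
    is the unweighted mean of the seasonal means that exist.  Sites with no
    record in any season are excluded with a logged warning (they cannot occur
    when the input is non-empty, but guard anyway).

    Returns a frame with columns ``site_id, pollutant, season, value_ugm3,
    n_weeks, clamped``.
    """
    rows = []
    for (site, pollutant), group in adjusted.groupby(["site_id", "pollutant"], sort=True):
        season_vals = {}
        for season in seasons:
            sub = group[group["season"] == season]
            if sub.empty:
                continue
            season_vals[season] = (
                float(sub["adjusted"].mean()),
                int(len(sub)),
                bool(sub["clamped"].any()),
            )
        if not season_vals:
            logger.warning("site %s has no adjusted record in any season; excluded", site)
            continue
        for season, (val, n, cl) in season_vals.items():
            rows.append((site, pollutant, season, val, n, cl))
        annual = float(np.mean([v[0] for v in season_vals.values()]))
        n_tot = int(sum(v[1] for v in season_vals.values()))
        cl_any = bool(any(v[2] for v in season_vals.values()))
        rows.append((site, pollutant, "annual", annual, n_tot, cl_any))
    return pd.DataFrame(
        rows, columns=["site_id", "pollutant", "season", "value_ugm3", "n_weeks", "clamped"]
    )
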
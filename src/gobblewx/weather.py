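"""Daily weather covariates from 15-minute station records.

Covariates follow the sunrise-anchored convention used in bioacoustic
gobbling surveys: each day's weather is summarized over the window from 30
minutes before to 150 minutes after local sunrise (the period holding the
bulk of gobbling activity).  Per day we compute mean temperature, relative
humidity, wind speed and barometric pressure over that window, the
day-over-day change in window-mean pressure, and a binary rain indicator.
Continuous covariates are z-scored over the pooled fitting frame; the rain
indicator stays 0/1.
"""

from __future__ import annotations

import dataclasses
from datetime import timedelta

import numpy as np
import pandas as pd

from .params import ConfigurationError

WINDOW_BEFORE = timedelta(minutes=30)
WINDOW_AFTER = timedelta(minutes=150)

#: raw -> scaled column names for the continuous covariates
SCALED_COLUMNS = {
    "temp_mean": "scaled_temp",
    "wind_mean": "scaled_wind",
    "pressure_change": "scaled_bp_change",
    "humidity_mean": "scaled_humidity",
}


class MissingDayError(ValueError):
    """A sunrise window with too few (or no) weather records."""


def sunrise_window(sunrise) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open interval [sunrise - 30 min, sunrise + 150 min).

    Every 15-minute record belongs to exactly one day's window because the
    interval is half-open; its duration is always 180 minutes.
    """
    sunrise = pd.Timestamp(sunrise)
    return sunrise - WINDOW_BEFORE, sunrise + WINDOW_AFTER


def records_in_window(records: pd.DataFrame, window) -> pd.DataFrame:
    start, end = window
    ts = pd.to_datetime(records["timestamp"])
    return records.loc[(ts >= start) & (ts < end)]


def daily_means(records: pd.DataFrame, window, min_records: int = 1) -> dict:
    """Arithmetic means of temperature, humidity, wind and pressure over
    the in-window records.

    Raises :class:`MissingDayError` when fewer than ``min_records`` records
    fall in the window, so an empty morning is flagged rather than silently
    averaged to zero.
    """
    sub = records_in_window(records, window)
    if len(sub) < max(min_records, 1):
        raise MissingDayError(
            f"window [{window[0]}, {window[1]}) has {len(sub)} records "
            f"(< {max(min_records, 1)})"
        )
    return {
        "temp_mean": float(sub["temperature"].mean()),
        "humidity_mean": float(sub["humidity"].mean()),
        "wind_mean": float(sub["wind"].mean()),
        "pressure_mean": float(sub["pressure"].mean()),
        "n_records": int(len(sub)),
    }


def pressure_change(daily_pressure_means: pd.Series) -> pd.Series:
    """Day-over-day change in morning-mean barometric pressure.

    ``daily_pressure_means`` is indexed by calendar date.  The value on day
    t is mean(t) - mean(t-1); the first day, and any day whose predecessor
    is missing from the index, is NaN (differences never span gaps).
    """
    if len(daily_pressure_means) < 2:
        raise ValueError("need at least 2 days of pressure means")
    s = daily_pressure_means.copy()
    s.index = pd.to_datetime(s.index)
    s = s.sort_index()
    full = s.reindex(pd.date_range(s.index[0], s.index[-1], freq="D"))
    diff = full.diff()
    return diff.reindex(s.index)


def rain_indicator(records: pd.DataFrame, window, threshold: float = 0.0) -> int:
    """1 if any in-window record shows precipitation strictly above
    ``threshold`` (default: any measurable amount), else 0."""
    sub = records_in_window(records, window)
    if len(sub) == 0:
        raise MissingDayError(f"window [{window[0]}, {window[1]}) has no records")
    return int((sub["precipitation"].to_numpy(dtype=float) > threshold).any())


def zscore(series, mean: float | None = None, sd: float | None = None):
    """Standardize a series to mean 0, sample SD 1 (ddof=1).

    Missing entries stay missing and are excluded from the moments.  The
    scaling constants are returned so new data can be transformed onto the
    identical scale.  A degenerate (constant) series raises.
    """
    s = pd.Series(series, dtype=float)
    if mean is None or sd is None:
        valid = s.dropna()
        if len(valid) < 2:
            raise ValueError("need >= 2 non-missing values to standardize")
        mean = float(valid.mean())
        sd = float(valid.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("zero-variance covariate cannot be standardized")
    return (s - mean) / sd, mean, sd


class CovariateScaler:
    """Transformer that z-scores the continuous daily covariates.

    Fitting learns the pooled all-site, all-year means and sample SDs
    (``means_``, ``scales_``); ``transform`` appends the ``scaled_*``
    columns.  The rain indicator is deliberately left unscaled: it is a
    0/1 dummy whose coefficient is interpreted as a rain-vs-no-rain
    contrast.
    """

    def __init__(self, columns=None):
        self.columns = columns

    def get_params(self, deep=True):
        return {"columns": self.columns}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _cols(self):
        return dict(self.columns) if self.columns is not None else dict(SCALED_COLUMNS)

    def fit(self, X: pd.DataFrame, y=None):
        self.means_ = {}
        self.scales_ = {}
        for raw in self._cols():
            valid = X[raw].dropna()
            if len(valid) < 2:
                raise ValueError(f"covariate {raw!r}: need >= 2 non-missing values")
            sd = float(valid.std(ddof=1))
            if sd <= 0:
                raise ValueError(f"covariate {raw!r} has zero variance")
            self.means_[raw] = float(valid.mean())
            self.scales_[raw] = sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for raw, scaled in self._cols().items():
            out[scaled] = (out[raw] - self.means_[raw]) / self.scales_[raw]
        return out

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def constants(self) -> pd.DataFrame:
        """Scaling constants as a tidy frame (for the sidecar file)."""
        rows = [
            {"covariate": raw, "scaled_column": scaled,
             "mean": self.means_[raw], "sd": self.scales_[raw]}
            for raw, scaled in self._cols().items()
        ]
        return pd.DataFrame(rows)


class CollinearityScreen:
    """Pairwise Pearson screen excluding covariates with |r| > threshold.

    The absolute value is intentional: a pair at r = -1 is exactly as
    redundant as one at r = +1.  When a pair is flagged, the member with
    the larger mean absolute correlation against all other covariates is
    dropped; ties break by column declaration order (the later column is
    dropped).  The full correlation matrix is always retained in
    ``correlation_`` regardless of exclusions.
    """

    def __init__(self, threshold: float = 0.60, min_pairs: int = 3):
        self.threshold = threshold
        self.min_pairs = min_pairs

    def get_params(self, deep=True):
        return {"threshold": self.threshold, "min_pairs": self.min_pairs}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[1] < 2:
            raise ValueError("need >= 2 covariates to screen")
        corr = X.corr(method="pearson", min_periods=self.min_pairs)
        self.correlation_ = corr
        self.unavailable_pairs_ = [
            (a, b)
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1:]
            if pd.isna(corr.loc[a, b])
        ]
        self.flagged_pairs_ = [
            (a, b, float(corr.loc[a, b]))
            for i, a in enumerate(corr.columns)
            for b in corr.columns[i + 1:]
            if pd.notna(corr.loc[a, b]) and abs(corr.loc[a, b]) > self.threshold
        ]
        order = list(X.columns)
        retained = list(order)
        dropped = []
        while True:
            flagged = [
                (a, b) for i, a in enumerate(retained) for b in retained[i + 1:]
                if pd.notna(corr.loc[a, b]) and abs(corr.loc[a, b]) > self.threshold
            ]
            if not flagged:
                break
            candidates = sorted({c for pair in flagged for c in pair}, key=order.index)
            sub = corr.loc[retained, retained].abs()
            np.fill_diagonal(sub.values, np.nan)
            mean_abs = sub.mean(axis=1, skipna=True)
            # larger mean |r| goes; declaration order breaks ties (later goes)
            worst = max(candidates, key=lambda c: (mean_abs[c], order.index(c)))
            retained.remove(worst)
            dropped.append(worst)
        self.retained_ = retained
        self.dropped_ = dropped
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def build_daily_covariates(
    weather: pd.DataFrame,
    sunrise: pd.DataFrame,
    min_records: int = 9,
    rain_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per site-day raw covariates from 15-minute records and sunrise times.

    Parameters
    ----------
    weather
        Station records with columns ``site, timestamp, temperature,
        humidity, wind, pressure, precipitation``.
    sunrise
        One row per site-day: ``site, date, sunrise`` (timestamp).
    min_records
        Completeness threshold: a window holding fewer 15-minute records is
        flagged missing (NaN covariates) rather than averaged.  The default
        of 9 demands three quarters of the 12 aligned steps.
    rain_threshold
        Trace-precipitation cutoff for the rain indicator; strictly-above
        comparison.

    Returns a tidy frame with one row per site-day: window means, pressure
    change (NaN on each site's first day and across gaps), and the rain
    indicator.  Scaled columns are added separately by
    :class:`CovariateScaler` so the constants can be reported.
    """
    weather = weather.copy()
    weather["timestamp"] = pd.to_datetime(weather["timestamp"])
    fields = ("temperature", "humidity", "wind", "pressure")
    rows = []
    for site, sun_site in sunrise.groupby("site", sort=False):
        recs = weather.loc[weather["site"] == site].sort_values("timestamp")
        ts = recs["timestamp"].to_numpy()
        # prefix sums turn each window mean into two lookups
        csum = {f: np.concatenate([[0.0], np.cumsum(recs[f].to_numpy(dtype=float))])
                for f in fields}
        wet_csum = np.concatenate(
            [[0], np.cumsum(recs["precipitation"].to_numpy(dtype=float) > rain_threshold)])
        for _, sr in sun_site.sort_values("date").iterrows():
            start, end = sunrise_window(sr["sunrise"])
            i = int(np.searchsorted(ts, start.to_datetime64(), side="left"))
            j = int(np.searchsorted(ts, end.to_datetime64(), side="left"))
            n = j - i
            row = {"site": site, "date": pd.Timestamp(sr["date"]).normalize(),
                   "n_records": n}
            if n < max(min_records, 1):
                row.update({"temp_mean": np.nan, "humidity_mean": np.nan,
                            "wind_mean": np.nan, "pressure_mean": np.nan,
                            "rain": np.nan, "missing": True})
            else:
                row.update({
                    "temp_mean": (csum["temperature"][j] - csum["temperature"][i]) / n,
                    "humidity_mean": (csum["humidity"][j] - csum["humidity"][i]) / n,
                    "wind_mean": (csum["wind"][j] - csum["wind"][i]) / n,
                    "pressure_mean": (csum["pressure"][j] - csum["pressure"][i]) / n,
                    "rain": int(wet_csum[j] - wet_csum[i] > 0),
                    "missing": False,
                })
            rows.append(row)
    daily = pd.DataFrame(rows)
    parts = []
    for site, grp in daily.groupby("site", sort=False):
        grp = grp.sort_values("date").copy()
        means = pd.Series(grp["pressure_mean"].to_numpy(), index=grp["date"])
        grp["pressure_change"] = pressure_change(means).to_numpy()
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)


def prepare_covariates(weather, sunrise, min_records: int = 9,
                       rain_threshold: float = 0.0,
                       scaler: CovariateScaler | None = None):
    """Full covariate pipeline: windowed means -> pressure differencing ->
    z-scaling.  Returns ``(covariates, scaler)``; pass a fitted ``scaler``
    to transform new data on the identical scale."""
    daily = build_daily_covariates(weather, sunrise, min_records=min_records,
                                   rain_threshold=rain_threshold)
    if scaler is None:
        # constants come from the pooled fitting frame: days with a defined
        # pressure change (each site's lead-in day never enters the model)
        scaler = CovariateScaler().fit(daily.loc[daily["pressure_change"].notna()])
    return scaler.transform(daily), scaler
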
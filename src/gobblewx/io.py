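"""CSV schemas for weather, sunrise, detection and model-frame files.

All files are plain CSV with ISO-8601 timestamps.

weather.csv     site, timestamp, temperature, humidity, wind, pressure,
                precipitation
sunrise.csv     site, date, sunrise
detections.csv  site, year, aru, timestamp, verified
counts.csv      site, year, day, date, count, units
covariates.csv  tidy per-site-day covariates (raw + scaled columns)
draws.csv       chain, iteration, parameter, value (tidy MCMC draws)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def read_weather_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    req = {"site", "timestamp", "temperature", "humidity", "wind",
           "pressure", "precipitation"}
    _require(df, req, path)
    return df


def read_sunrise_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date", "sunrise"])
    _require(df, {"site", "date", "sunrise"}, path)
    return df


def read_detections_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    _require(df, {"site", "year", "aru", "timestamp", "verified"}, path)
    return df


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _require(df, {"site", "year", "day", "count", "units"}, path)
    return df


def read_covariates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    _require(df, {"site", "date"}, path)
    return df


def write_draws_csv(chains: dict, path) -> None:
    """Tidy draws file: one row per (chain, iteration, parameter)."""
    rows = []
    for name, arr in chains.items():
        arr = np.asarray(arr)
        for c in range(arr.shape[0]):
            rows.append(pd.DataFrame({
                "chain": c, "iteration": np.arange(arr.shape[1]),
                "parameter": name, "value": arr[c]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_draws_csv(path) -> dict:
    df = pd.read_csv(path)
    _require(df, {"chain", "iteration", "parameter", "value"}, path)
    chains = {}
    for name, grp in df.groupby("parameter", sort=False):
        wide = grp.pivot(index="chain", columns="iteration", values="value")
        chains[name] = wide.to_numpy()
    return chains


def _require(df: pd.DataFrame, columns: set, path) -> None:
    missing = columns - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path)}: missing columns {sorted(missing)}")
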
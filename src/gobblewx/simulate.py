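"""Synthetic weather streams and gobble-count datasets with known truth.

The generator reproduces the statistical structure the state-space model
assumes — a 1 March–31 May season of 15-minute weather records per site,
sunrise-anchored covariates, and daily counts driven by the latent
log-abundance recursion — with every true parameter retained, so recovery
of the weather coefficients can be tested end to end without any field
data.

Weather features emulated: a rising seasonal temperature trend with
autocorrelated day-to-day noise and a diurnal cycle, autocorrelated
humidity (clipped to 0–100) and wind (non-negative), barometric pressure
as a random walk reflected at physical bounds, and rain occurring in
multi-day spells via a two-state (dry/wet) Markov chain whose marginal wet
probability and day-to-day persistence are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .params import BETA_COLUMNS, BETA_NAMES, ConfigurationError, ModelParams
from . import weather as wx

SEASON_START = (3, 1)  # 1 March; season runs through 31 May (92 days)


@dataclass
class WeatherControls:
    """Means, SDs and autocorrelations of the synthetic weather streams.

    Defaults describe a southeastern-US spring: temperature climbing from
    ~10 to ~24 °C over the season, humid mornings, light wind, pressure
    near 1013 mb, and rain on roughly a quarter of days arriving in
    multi-day spells.
    """

    temp_start: float = 10.0       # seasonal daily-mean trend, °C
    temp_end: float = 24.0
    temp_sd: float = 3.0           # day-level AR(1) noise SD
    temp_ar: float = 0.7
    temp_diurnal_amp: float = 5.0  # °C; coolest near dawn
    temp_quarter_sd: float = 0.3   # within-day 15-min jitter
    humidity_mean: float = 75.0
    humidity_sd: float = 10.0
    humidity_ar: float = 0.5
    wind_mean: float = 8.0         # kph
    wind_sd: float = 4.0
    wind_ar: float = 0.3
    pressure_start: float = 1013.0  # mb
    pressure_step_sd: float = 0.15  # per 15-min reflected random-walk step
    pressure_bounds: tuple = (980.0, 1040.0)
    rain_probability: float = 0.25  # marginal P(wet day)
    rain_persistence: float = 0.4   # lag-1 autocorrelation of the wet state
    rain_amount_scale: float = 0.5  # mm per 15-min on wet days (exponential)

    def validate(self):
        for name in ("temp_sd", "temp_quarter_sd", "humidity_sd", "wind_sd",
                     "pressure_step_sd", "temp_diurnal_amp", "rain_amount_scale"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.rain_probability <= 1.0:
            raise ConfigurationError("rain_probability must be in [0, 1]")
        if not 0.0 <= self.rain_persistence < 1.0:
            raise ConfigurationError("rain_persistence must be in [0, 1)")
        for name in ("temp_ar", "humidity_ar", "wind_ar"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (-1, 1)")
        lo, hi = self.pressure_bounds
        if not lo < self.pressure_start < hi:
            raise ConfigurationError("pressure_start must lie inside pressure_bounds")


@dataclass
class SimulationConfig:
    """Study design of a synthetic dataset.

    ``n_days`` counts model days per site-year (the 1 Mar–31 May season
    holds 92); one extra lead-in day of weather is always generated so the
    pressure difference exists on the first model day.  ``units`` may be a
    single integer (constant effort), a mapping ``(site, year) -> int``,
    or a mapping to per-day arrays.
    """

    n_sites: int = 5
    n_years: int = 3
    n_days: int = 92
    units: object = 10
    true_params: ModelParams | None = None
    weather_controls: WeatherControls = field(default_factory=WeatherControls)
    first_year: int = 2016
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 2:
            raise ConfigurationError("n_days must be >= 2")
        if self.n_sites < 1 or self.n_years < 1:
            raise ConfigurationError("need >= 1 site and year")
        self.weather_controls.validate()
        if self.true_params is None:
            self.true_params = ModelParams(
                site_effect=np.zeros(self.n_sites),
                year_effect=np.zeros(self.n_years),
            )
        if len(self.true_params.site_effect) != self.n_sites:
            raise ConfigurationError("site_effect length must equal n_sites")
        if len(self.true_params.year_effect) != self.n_years:
            raise ConfigurationError("year_effect length must equal n_years")

    @property
    def sites(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_sites)]

    @property
    def years(self) -> list:
        return [self.first_year + i for i in range(self.n_years)]

    def units_for(self, site: str, year: int, n_days: int) -> np.ndarray:
        u = self.units
        if isinstance(u, dict):
            u = u[(site, year)]
        arr = np.broadcast_to(np.asarray(u, dtype=float), (n_days,)).copy()
        if np.any(arr < 1):
            raise ConfigurationError("units must be >= 1 on every day")
        return arr


@dataclass
class SimulatedDataset:
    """Weather records, covariates, counts and the retained truth."""

    weather: pd.DataFrame
    sunrise: pd.DataFrame
    covariates: pd.DataFrame
    counts: pd.DataFrame          # site, year, day, date, count, units
    truth: ModelParams
    scaler: wx.CovariateScaler
    config: SimulationConfig


def synthetic_sunrise(site_index: int, dates) -> pd.Series:
    """Smooth seasonal sunrise times (no ephemeris needed).

    Sunrise drifts earlier over the spring season, from ~06:50 on 1 March
    toward ~05:25 by late May, following a gentle cosine ramp; each site
    gets a fixed few-minute longitude offset.  An externally supplied
    sunrise table can be used instead anywhere one is accepted.
    """
    dates = pd.to_datetime(pd.Index(dates))
    doy = dates.dayofyear.to_numpy(dtype=float)
    frac = np.clip((doy - 60.0) / 92.0, 0.0, 1.2)  # 0 at 1 Mar, 1 at 31 May
    minutes = 410.0 - 85.0 * (1 - np.cos(np.pi * frac)) / 2.0  # 06:50 -> 05:25
    minutes = minutes + 2.5 * site_index
    out = [d.normalize() + timedelta(minutes=float(m)) for d, m in zip(dates, minutes)]
    return pd.Series(out, index=dates)


def _ar1(rng, n, mean, sd, phi):
    """Stationary Gaussian AR(1) around ``mean``."""
    x = np.empty(n)
    innov_sd = sd * np.sqrt(max(1.0 - phi ** 2, 0.0))
    x[0] = mean + sd * rng.standard_normal() if sd > 0 else mean
    for t in range(1, n):
        x[t] = mean + phi * (x[t - 1] - mean) + innov_sd * rng.standard_normal()
    return x


def simulate_rain_days(rng, n_days, probability, persistence):
    """Dry/wet day sequence from a two-state Markov chain.

    Transition P(wet_t | state_{t-1}) = (1-c)*pi + c*1{wet_{t-1}} with
    pi = ``probability`` and c = ``persistence``; the stationary marginal
    wet frequency is exactly pi and c is the lag-1 autocorrelation, so
    higher persistence yields longer multi-day rain spells at the same
    overall frequency.
    """
    if not 0.0 <= probability <= 1.0:
        raise ConfigurationError("rain probability must be in [0, 1]")
    wet = np.zeros(n_days, dtype=int)
    p = probability
    c = persistence
    wet[0] = rng.random() < p
    for t in range(1, n_days):
        p_wet = (1 - c) * p + c * wet[t - 1]
        wet[t] = rng.random() < p_wet
    return wet


def rain_stationary_frequency(probability, persistence):
    """Closed-form stationary wet-day frequency of the simulated chain."""
    return probability


def _reflect(x, lo, hi):
    """Reflect a scalar into [lo, hi]."""
    width = hi - lo
    if width <= 0:
        raise ConfigurationError("invalid pressure bounds")
    y = (x - lo) % (2 * width)
    return lo + (width - abs(y - width))


def simulate_weather(config: SimulationConfig, site: str, dates, rng=None) -> pd.DataFrame:
    """15-minute weather records for one site over ``dates`` (full days).

    Each day contributes 96 quarter-hour records (00:00–23:45), which
    always covers the sunrise window.  Temperature = seasonal trend +
    day-level AR(1) + diurnal cosine (coolest ~05:00) + quarter-hour
    jitter; humidity and wind are day-level AR(1) held within physical
    bounds; pressure is a reflected random walk; rain days carry strictly
    positive precipitation in every quarter-hour, dry days zero.
    """
    cw = config.weather_controls
    cw.validate()
    dates = pd.to_datetime(pd.Index(dates))
    if len(dates) == 0:
        raise ConfigurationError("day range is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = len(dates)
    frac = np.arange(n) / max(n - 1, 1)
    temp_trend = cw.temp_start + (cw.temp_end - cw.temp_start) * frac
    temp_day = temp_trend + _ar1(rng, n, 0.0, cw.temp_sd, cw.temp_ar)
    hum_day = np.clip(_ar1(rng, n, cw.humidity_mean, cw.humidity_sd, cw.humidity_ar), 0.0, 100.0)
    wind_day = np.maximum(_ar1(rng, n, cw.wind_mean, cw.wind_sd, cw.wind_ar), 0.0)
    wet = simulate_rain_days(rng, n, cw.rain_probability, cw.rain_persistence)

    lo, hi = cw.pressure_bounds
    steps_per_day = 96
    n_steps = n * steps_per_day
    tod = np.arange(steps_per_day) * 15 / 60.0  # hours
    diurnal = -np.cos(2 * np.pi * (tod - 17.0) / 24.0)  # max ~17:00, min ~05:00

    temps = (np.repeat(temp_day, steps_per_day)
             + np.tile(cw.temp_diurnal_amp * diurnal, n))
    if cw.temp_quarter_sd > 0:
        temps = temps + cw.temp_quarter_sd * rng.standard_normal(n_steps)
    # reflected random walk == folding of the unbounded walk into the bounds
    if cw.pressure_step_sd > 0:
        walk = cw.pressure_start + np.cumsum(
            cw.pressure_step_sd * rng.standard_normal(n_steps))
        pressure = _reflect(walk, lo, hi)
    else:
        pressure = np.full(n_steps, cw.pressure_start)
    precip = np.zeros(n_steps)
    wet_steps = np.repeat(wet.astype(bool), steps_per_day)
    if wet_steps.any():
        precip[wet_steps] = rng.exponential(
            cw.rain_amount_scale, int(wet_steps.sum())) + 1e-6
    offsets = np.arange(steps_per_day) * np.timedelta64(15, "m")
    timestamps = np.repeat(dates.to_numpy(), steps_per_day) + np.tile(offsets, n)
    return pd.DataFrame({
        "site": site,
        "timestamp": timestamps,
        "temperature": temps,
        "humidity": np.repeat(hum_day, steps_per_day),
        "wind": np.repeat(wind_day, steps_per_day),
        "pressure": pressure,
        "precipitation": precip,
    })


def simulate_gobbling(covariates: pd.DataFrame, units, params: ModelParams,
                      seed=0, site_index: int = 0, year_index: int = 0,
                      log_n0: float | None = None):
    """Forward-simulate daily gobble counts from the state-space process.

    ``covariates`` must carry the model-frame columns (scaled weather plus
    the 0/1 rain indicator) already on the scale the fitting stage uses,
    one row per day in order.  The latent recursion is

        mu_t   = rho*logN[t-1] + site + beta.x_t + year + log(units_t)
        r_t    ~ Normal(mu_t, sigma_process)
        logN_t = logN[t-1] + r_t
        y_t    ~ Poisson(exp(logN_t))

    Returns ``(counts, log_n)``: integer counts and the latent trajectory,
    both length ``len(covariates)``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = len(covariates)
    for col in BETA_COLUMNS.values():
        if col not in covariates.columns:
            raise ValueError(f"covariate column {col!r} missing")
        bad = covariates[col].isna()
        if bad.any():
            raise ValueError(f"missing covariate {col!r} on day index "
                             f"{int(np.flatnonzero(bad.to_numpy())[0])}")
    X = covariates[[BETA_COLUMNS[n] for n in BETA_NAMES]].to_numpy(dtype=float)
    u = np.broadcast_to(np.asarray(units, dtype=float), (T,))
    if np.any(u < 1):
        raise ConfigurationError("units must be >= 1")
    site_eff = float(params.site_effect[site_index])
    year_eff = float(params.year_effect[year_index])
    betas = params.betas
    c = site_eff + year_eff

    if log_n0 is None:
        if params.log_n0 is not None:
            raise ValueError("pass log_n0 explicitly or leave params.log_n0 unset")
        # equilibrium of the deterministic recursion when rho < 0, else log 20
        base = c + np.log(u.mean())
        log_n0 = -base / params.rho if params.rho < 0 else np.log(20.0)

    log_n = np.empty(T)
    log_n[0] = log_n0
    for t in range(1, T):
        mu = params.rho * log_n[t - 1] + c + X[t] @ betas + np.log(u[t])
        r = mu + params.sigma_process * rng.standard_normal()
        log_n[t] = log_n[t - 1] + r
    counts = rng.poisson(np.exp(np.clip(log_n, None, 30.0)))
    return counts.astype(int), log_n


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a complete dataset: weather, sunrise, covariates, counts.

    One master seed spawns independent substreams per site-year, so any
    site-year is reproducible in isolation.  Weather starts one day before
    the model frame so the pressure difference exists on model day 1; the
    covariate scaler is fit on the pooled all-site, all-year frame exactly
    as the fitting stage would.
    """
    cfg = config
    master = np.random.SeedSequence(cfg.seed)
    streams = master.spawn(cfg.n_sites * cfg.n_years + 1)
    weather_frames, sunrise_frames = [], []
    for yi, year in enumerate(cfg.years):
        start = pd.Timestamp(date(year, *SEASON_START)) - pd.Timedelta(days=1)
        dates = pd.date_range(start, periods=cfg.n_days + 1, freq="D")
        for si, site in enumerate(cfg.sites):
            rng = np.random.default_rng(streams[yi * cfg.n_sites + si])
            wdf = simulate_weather(cfg, site, dates, rng=rng)
            weather_frames.append(wdf)
            sun = synthetic_sunrise(si, dates)
            sunrise_frames.append(pd.DataFrame(
                {"site": site, "date": sun.index, "sunrise": sun.to_numpy()}))
    weather_df = pd.concat(weather_frames, ignore_index=True)
    sunrise_df = pd.concat(sunrise_frames, ignore_index=True)

    covs, scaler = wx.prepare_covariates(weather_df, sunrise_df)
    covs["year"] = covs["date"].dt.year
    # model frame: drop each site-year's lead-in day (no pressure change)
    model_covs = covs.loc[covs["pressure_change"].notna()].copy()

    count_rng = np.random.default_rng(streams[-1])
    truth = cfg.true_params
    log_n0_map, log_n_map = {}, {}
    count_rows = []
    for yi, year in enumerate(cfg.years):
        for si, site in enumerate(cfg.sites):
            sub = model_covs[(model_covs["site"] == site)
                             & (model_covs["year"] == year)].sort_values("date")
            u = cfg.units_for(site, year, len(sub))
            counts, log_n = simulate_gobbling(
                sub, u, truth, seed=count_rng, site_index=si, year_index=yi)
            log_n0_map[(site, year)] = float(log_n[0])
            log_n_map[(site, year)] = log_n
            count_rows.append(pd.DataFrame({
                "site": site, "year": year,
                "day": np.arange(1, len(sub) + 1),
                "date": sub["date"].to_numpy(),
                "count": counts, "units": u,
            }))
    counts_df = pd.concat(count_rows, ignore_index=True)
    truth.log_n0 = log_n0_map
    truth.log_n = log_n_map
    return SimulatedDataset(weather=weather_df, sunrise=sunrise_df,
                            covariates=covs, counts=counts_df, truth=truth,
                            scaler=scaler, config=cfg)


def model_frame(ds: SimulatedDataset) -> pd.DataFrame:
    """Join counts and scaled covariates into the frame the model fits."""
    covs = ds.covariates.loc[ds.covariates["pressure_change"].notna()]
    cols = ["site", "year", "date", "rain",
            "scaled_temp", "scaled_wind", "scaled_bp_change", "scaled_humidity"]
    return ds.counts.merge(covs[cols], on=["site", "year", "date"], how="left")


def write_dataset(ds: SimulatedDataset, outdir):
    """CSV writers matching the real-data reader schemas, plus a truth
    sidecar (JSON) for recovery tests."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.weather.to_csv(outdir / "weather.csv", index=False)
    ds.sunrise.to_csv(outdir / "sunrise.csv", index=False)
    ds.covariates.to_csv(outdir / "covariates.csv", index=False)
    ds.counts.to_csv(outdir / "counts.csv", index=False)
    ds.scaler.constants().to_csv(outdir / "scaling_constants.csv", index=False)
    t = ds.truth
    sidecar = {
        "betas": t.beta_dict(),
        "site_effect": t.site_effect.tolist(),
        "year_effect": t.year_effect.tolist(),
        "sigma_year": t.sigma_year,
        "sigma_process": t.sigma_process,
        "rho": t.rho,
        "log_n0": {f"{k[0]}|{k[1]}": v for k, v in (t.log_n0 or {}).items()},
    }
    (outdir / "truth.json").write_text(json.dumps(sidecar, indent=2))
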
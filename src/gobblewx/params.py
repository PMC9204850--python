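"""Shared parameter containers for the gobbling state-space model.

The model decomposes daily gobbling counts into a latent log-abundance
process and a Poisson observation process.  ``ModelParams`` holds every
quantity of that model: weather coefficients on standardized covariates,
per-site intercepts, year random effects, the density-dependence
coefficient on lagged log-abundance, and the two variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical ordering of the weather coefficients
BETA_NAMES = ("temperature", "wind", "bp", "humidity", "precipitation")

#: model-frame column that carries each weather covariate
BETA_COLUMNS = {
    "temperature": "scaled_temp",
    "wind": "scaled_wind",
    "bp": "scaled_bp_change",
    "humidity": "scaled_humidity",
    "precipitation": "rain",
}


class ConfigurationError(ValueError):
    """Raised when a simulation or model configuration is invalid."""


@dataclass
class ModelParams:
    """Full parameter set of the state-space model.

    Parameters
    ----------
    beta_temperature, beta_wind, beta_bp, beta_humidity, beta_precipitation
        Coefficients on the standardized weather covariates (the
        precipitation covariate is a raw 0/1 rain indicator, never scaled).
    site_effect
        Per-site intercept of the expected daily growth rate, one entry
        per site (no global intercept).
    year_effect
        Year random effects, one entry per year, centred at zero.
    sigma_year
        Standard deviation of the year random effects.
    sigma_process
        Standard deviation of the realized growth rate around its
        expectation (process noise on the log scale).
    rho
        Coefficient on lagged log-abundance in the growth-rate predictor.
        ``rho = 0`` gives a covariate-driven random walk; negative values
        give Gompertz-style mean reversion.
    log_n0
        Optional per-site-year initial latent log-abundance, keyed by
        ``(site, year)``.  When absent, simulators start at the implied
        equilibrium and fitters centre a vague prior on the data.
    log_n
        Optional latent trajectories (site-year keyed arrays); populated by
        the simulator so recovery tests can compare against truth.
    """

    beta_temperature: float = 0.0
    beta_wind: float = 0.0
    beta_bp: float = 0.0
    beta_humidity: float = 0.0
    beta_precipitation: float = 0.0
    site_effect: np.ndarray = field(default_factory=lambda: np.zeros(1))
    year_effect: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sigma_year: float = 0.05
    sigma_process: float = 0.15
    rho: float = 0.0
    log_n0: dict | None = None
    log_n: dict | None = None

    def __post_init__(self):
        self.site_effect = np.asarray(self.site_effect, dtype=float)
        self.year_effect = np.asarray(self.year_effect, dtype=float)
        if self.sigma_process < 0:
            raise ConfigurationError("sigma_process must be >= 0")
        if self.sigma_year < 0:
            raise ConfigurationError("sigma_year must be >= 0")

    @property
    def betas(self) -> np.ndarray:
        """Weather coefficients in canonical order."""
        return np.array([getattr(self, f"beta_{n}") for n in BETA_NAMES])

    def beta_dict(self) -> dict:
        return dict(zip(BETA_NAMES, self.betas))


@dataclass
class PriorSpec:
    """Priors: vague normals on coefficients, vague gammas on precisions.

    ``coefficient_precision`` applies to every site effect, weather
    coefficient and the density-dependence coefficient (Normal(0, 1/prec)).
    The Gamma(shape, rate) prior applies to both the process precision and
    the year-effect precision.  The initial latent state of each site-year
    gets Normal(centre, init_state_sd^2) with a data-derived centre.
    """

    coefficient_precision: float = 0.001
    precision_shape: float = 0.001
    precision_rate: float = 0.001
    init_state_sd: float = 10.0

    def __post_init__(self):
        for name in ("coefficient_precision", "precision_shape", "precision_rate", "init_state_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def coefficient_sd(self) -> float:
        return 1.0 / np.sqrt(self.coefficient_precision)


@dataclass
class McmcSettings:
    """Sampler run lengths.  Defaults follow the 3-chain, 2,500 burn-in,
    10,000-iteration, thin-10 configuration; smaller values are appropriate
    for simulation studies."""

    n_chains: int = 3
    n_burnin: int = 2500
    n_iterations: int = 10000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self):
        if self.n_chains < 2:
            raise ConfigurationError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.n_iterations < self.thin:
            raise ConfigurationError("n_iterations must be >= thin")

    @property
    def n_kept(self) -> int:
        return self.n_iterations // self.thin
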
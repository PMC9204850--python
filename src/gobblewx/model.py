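"""Bayesian hierarchical state-space model for daily gobbling counts.

Process model, per site k and year i (subscripts suppressed):

    r_expected(t) = rho*logN[t-1] + Site(k) + b_temp*x_temp(t)
                    + b_wind*x_wind(t) + b_bp*dx_bp(t) + b_hum*x_hum(t)
                    + b_precip*rain(t) + Year(i) + log(Units(t))
    r_t ~ Normal(r_expected(t), sigma_process^2)
    logN[t] = logN[t-1] + r_t

Observation model: y_t ~ Poisson(N_t) with N_t = exp(logN[t]); the latent
state is log-abundance of gobbles, and the Units offset enters the growth
rate with a fixed unit coefficient.  Priors are vague: Normal(0, 1/0.001)
on every coefficient, Gamma(0.001, 0.001) on the process and year-effect
precisions, and a wide data-centred Normal on each initial state.

Posterior sampling is Gibbs with exact conjugate updates wherever the
full conditional is available in closed form — the coefficient block
(site intercepts, weather coefficients, year effects, and optionally rho)
is multivariate normal given the latent states, and both precisions are
Gamma — while the latent log-abundance states use adaptive random-walk
Metropolis in an even/odd checkerboard (each state's conditional depends
only on its two neighbours, so alternating parities update a thousand
states in a handful of vector operations).  Step sizes adapt toward 44%
acceptance during burn-in and are frozen afterwards, preserving the
stationary distribution of the recorded draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_solve, cholesky, solve_triangular
from sklearn.base import BaseEstimator

from .params import (BETA_COLUMNS, BETA_NAMES, ConfigurationError, McmcSettings,
                     ModelParams, PriorSpec)
from . import diagnostics as dx

_ADAPT_TARGET = 0.44  # scalar-update acceptance target
_EXP_CAP = 40.0       # reject latent proposals implying exp() overflow


def r_expected(log_n_prev: float, covariates, params: ModelParams,
               site_index: int = 0, year_index: int = 0, units: float = 1.0) -> float:
    """Expected daily growth rate of gobbling activity.

    ``covariates`` maps the model-frame column names (``scaled_temp``,
    ``scaled_wind``, ``scaled_bp_change``, ``scaled_humidity``, ``rain``)
    to that day's values.  ``units`` must be >= 1; its log enters with a
    fixed coefficient of one (an exposure offset).
    """
    if units < 1:
        raise ValueError("units must be >= 1")
    x = []
    for name in BETA_NAMES:
        col = BETA_COLUMNS[name]
        if col not in covariates or pd.isna(covariates[col]):
            raise ValueError(f"missing covariate {col!r}")
        x.append(float(covariates[col]))
    return float(
        params.rho * log_n_prev
        + params.site_effect[site_index]
        + np.dot(params.betas, x)
        + params.year_effect[year_index]
        + np.log(units)
    )


@dataclass
class ModelData:
    """Padded site-year arrays the likelihood and sampler operate on."""

    sites: list
    years: list
    series_keys: list          # (site, year) per series
    site_idx: np.ndarray       # (S,)
    year_idx: np.ndarray       # (S,)
    y: np.ndarray              # (S, T) float, NaN where unobserved
    obs_mask: np.ndarray       # (S, T)
    log_u: np.ndarray          # (S, T)
    X: np.ndarray              # (S, T, 5) covariates in canonical order
    valid: np.ndarray          # (S, T) day belongs to the frame
    trans: np.ndarray          # (S, T) transition t-1 -> t is modelled
    seg_start: np.ndarray      # (S, T) state with no incoming transition
    m0: np.ndarray             # (S,) initial-state prior centres
    lengths: np.ndarray        # (S,) true series lengths

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModelData":
        """Build from a tidy model frame with columns ``site, year, day,
        count, units`` plus the five covariate columns.  Counts may be NaN
        (missing observation days); covariate gaps break the transition
        chain rather than being imputed."""
        req = {"site", "year", "day", "count", "units", *BETA_COLUMNS.values()}
        missing = req - set(frame.columns)
        if missing:
            raise ValueError(f"model frame missing columns: {sorted(missing)}")
        frame = frame.sort_values(["site", "year", "day"])
        cnt = frame["count"].to_numpy(dtype=float)
        finite = np.isfinite(cnt)
        if np.any(cnt[finite] < 0) or np.any(cnt[finite] != np.round(cnt[finite])):
            raise ValueError("counts must be non-negative integers")
        if np.any(frame["units"].to_numpy(dtype=float) < 1):
            raise ValueError("units must be >= 1 on every day")

        sites = list(pd.unique(frame["site"]))
        years = sorted(pd.unique(frame["year"]))
        groups = list(frame.groupby(["site", "year"], sort=False))
        S = len(groups)
        T = max(len(g) for _, g in groups)
        y = np.full((S, T), np.nan)
        log_u = np.zeros((S, T))
        X = np.zeros((S, T, 5))
        valid = np.zeros((S, T), dtype=bool)
        trans = np.zeros((S, T), dtype=bool)
        site_idx = np.zeros(S, dtype=int)
        year_idx = np.zeros(S, dtype=int)
        m0 = np.zeros(S)
        lengths = np.zeros(S, dtype=int)
        keys = []
        xcols = [BETA_COLUMNS[n] for n in BETA_NAMES]
        for s, ((site, year), g) in enumerate(groups):
            n = len(g)
            if n < 2:
                raise ValueError(f"site-year ({site}, {year}) has fewer than 2 days")
            keys.append((site, year))
            site_idx[s] = sites.index(site)
            year_idx[s] = years.index(year)
            lengths[s] = n
            y[s, :n] = g["count"].to_numpy(dtype=float)
            log_u[s, :n] = np.log(g["units"].to_numpy(dtype=float))
            xs = g[xcols].to_numpy(dtype=float)
            X[s, :n] = np.nan_to_num(xs)
            valid[s, :n] = True
            days = g["day"].to_numpy()
            consec = np.concatenate([[False], np.diff(days) == 1])
            cov_ok = np.isfinite(xs).all(axis=1)
            trans[s, :n] = consec & cov_ok
            obs = np.isfinite(y[s, :n]) & (y[s, :n] > 0)
            first = y[s, :n][obs][0] if obs.any() else 1.0
            m0[s] = np.log(first + 1.0)
        obs_mask = np.isfinite(y) & valid
        # per-covariate variance over modelled transitions
        rows = trans.nonzero()
        xv = X[rows]
        for j, name in enumerate(BETA_NAMES):
            if np.var(xv[:, j]) <= 0:
                raise ConfigurationError(
                    f"covariate {BETA_COLUMNS[name]!r} has zero variance over the "
                    "fitting frame (should have been screened)")
        seg_start = valid & ~trans
        return cls(sites, years, keys, site_idx, year_idx, y, obs_mask, log_u,
                   X, valid, trans, seg_start, m0, lengths)

    def pad_latents(self, log_n: dict) -> np.ndarray:
        out = np.zeros(self.y.shape)
        for s, key in enumerate(self.series_keys):
            if key not in log_n:
                raise ValueError(f"latent trajectory missing for {key}")
            arr = np.asarray(log_n[key], dtype=float)
            if len(arr) != self.lengths[s]:
                raise ValueError(f"latent trajectory for {key} has length "
                                 f"{len(arr)}, expected {self.lengths[s]}")
            out[s, :self.lengths[s]] = arr
        return out


def joint_log_density(md: ModelData, params: ModelParams, priors: PriorSpec,
                      estimate_rho: bool = True) -> float:
    """Log joint density of data, latent states and parameters.

    Sums (a) Normal log-densities of each modelled growth step around its
    expectation, (b) the Poisson log-pmf of every observed count given
    N_t = exp(logN_t), (c) coefficient, random-effect, initial-state and
    precision priors.  Missing observation days contribute only process
    terms.  Raises if the result is non-finite, naming the offending term.
    """
    if params.log_n is None:
        raise ValueError("params.log_n must hold the latent trajectories")
    logN = md.pad_latents(params.log_n)
    c = params.site_effect[md.site_idx] + params.year_effect[md.year_idx]
    w = md.X @ params.betas + md.log_u
    mu = np.zeros_like(logN)
    mu[:, 1:] = (1.0 + params.rho) * logN[:, :-1] + c[:, None] + w[:, 1:]
    r_to = logN  # logN[t] = logN[t-1] + r_t  =>  target of each step
    proc = stats.norm.logpdf(r_to[md.trans], mu[md.trans], params.sigma_process).sum()
    lam = np.exp(logN[md.obs_mask])
    obs = stats.poisson.logpmf(md.y[md.obs_mask].astype(int), lam).sum()
    sd0 = priors.coefficient_sd
    coef = stats.norm.logpdf(params.site_effect, 0, sd0).sum()
    coef += stats.norm.logpdf(params.betas, 0, sd0).sum()
    if estimate_rho:
        coef += stats.norm.logpdf(params.rho, 0, sd0)
    coef += stats.norm.logpdf(params.year_effect, 0, params.sigma_year).sum()
    # boolean indexing is row-major, so repeating m0 by per-row counts aligns
    coef += stats.norm.logpdf(logN[md.seg_start],
                              np.repeat(md.m0, md.seg_start.sum(axis=1)),
                              priors.init_state_sd).sum()
    tau_p = params.sigma_process ** -2
    tau_y = params.sigma_year ** -2
    prec = stats.gamma.logpdf(tau_p, priors.precision_shape,
                              scale=1.0 / priors.precision_rate)
    prec += stats.gamma.logpdf(tau_y, priors.precision_shape,
                               scale=1.0 / priors.precision_rate)
    pieces = {"process": proc, "observation": obs, "priors": coef,
              "precisions": prec}
    for name, val in pieces.items():
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite log-density term: {name}")
    return float(proc + obs + coef + prec)


def _run_chain(md: ModelData, *, n_burnin, n_iterations, thin, prior: PriorSpec,
               rng: np.random.Generator, estimate_rho, rho_fixed, chain_jitter,
               store_latent):
    S, T = md.y.shape
    K, I = len(md.sites), len(md.years)
    p_static = K + 5 + I
    p = p_static + (1 if estimate_rho else 0)

    ts, tt = md.trans.nonzero()
    n_tr = len(ts)
    Zs = np.zeros((n_tr, p_static))
    Zs[np.arange(n_tr), md.site_idx[ts]] = 1.0
    Zs[:, K:K + 5] = md.X[ts, tt]
    Zs[np.arange(n_tr), K + 5 + md.year_idx[ts]] = 1.0
    off = md.log_u[ts, tt]

    y = np.nan_to_num(md.y, nan=0.0)
    logN = np.where(md.valid, np.log(np.clip(y, 1.0, None)), 0.0)
    theta = chain_jitter * prior.coefficient_sd * rng.standard_normal(p)
    rho = theta[-1] if estimate_rho else float(rho_fixed)
    tau = 4.0
    tau_year = 4.0
    sd0_sq = prior.init_state_sd ** 2
    a0, b0 = prior.precision_shape, prior.precision_rate

    step = np.full((S, T), 0.1)
    m0_col = md.m0[:, None]
    par_masks = [md.valid.copy() for _ in range(2)]
    for par in (0, 1):
        par_masks[par][:, (1 - par)::2] = False

    n_keep = n_iterations // thin
    out = {name: np.empty(n_keep) for name in
           [f"site_{s}" for s in md.sites]
           + [f"beta_{b}" for b in BETA_NAMES]
           + [f"year_{yr}" for yr in md.years]
           + (["rho"] if estimate_rho else [])
           + ["sigma_process", "sigma_year"]}
    latents = np.empty((n_keep, S, T)) if store_latent else None
    acc_sum = 0.0
    acc_n = 0
    kept = 0

    for it in range(n_burnin + n_iterations):
        adapting = it < n_burnin
        # --- latent states: even/odd checkerboard Metropolis ---
        c = theta[md.site_idx] + theta[K + 5 + md.year_idx]
        w = md.X @ theta[K:K + 5] + md.log_u
        phi = 1.0 + rho
        for par in (0, 1):
            mask = par_masks[par]
            a_in = np.zeros((S, T))
            a_in[:, 1:] = phi * logN[:, :-1] + c[:, None] + w[:, 1:]
            prop = logN + step * rng.standard_normal((S, T))
            d = np.where(md.obs_mask,
                         y * (prop - logN)
                         - (np.exp(np.minimum(prop, _EXP_CAP))
                            - np.exp(np.minimum(logN, _EXP_CAP))), 0.0)
            d += np.where(md.trans,
                          -0.5 * tau * ((prop - a_in) ** 2 - (logN - a_in) ** 2), 0.0)
            b_out = np.zeros((S, T))
            b_out[:, :-1] = logN[:, 1:] - c[:, None] - w[:, 1:]
            d_out = np.zeros((S, T))
            d_out[:, :-1] = np.where(
                md.trans[:, 1:],
                -0.5 * tau * ((b_out[:, :-1] - phi * prop[:, :-1]) ** 2
                              - (b_out[:, :-1] - phi * logN[:, :-1]) ** 2), 0.0)
            d += d_out
            d += np.where(md.seg_start,
                          -0.5 / sd0_sq * ((prop - m0_col) ** 2
                                           - (logN - m0_col) ** 2), 0.0)
            d = np.where(np.abs(prop) > _EXP_CAP, -np.inf, d)
            accept = (np.log(rng.random((S, T))) < d) & mask
            logN = np.where(accept, prop, logN)
            if adapting:
                eta = min(0.1, 2.0 / np.sqrt(it + 1.0))
                move = np.where(mask, accept.astype(float) - _ADAPT_TARGET, 0.0)
                step *= np.exp(eta * move)
            else:
                acc_sum += accept[mask].sum()
                acc_n += mask.sum()

        # --- coefficient block: exact conjugate MVN draw ---
        prev = logN[ts, tt - 1]
        resp = logN[ts, tt] - prev - off
        if estimate_rho:
            Z = np.column_stack([Zs, prev])
        else:
            Z = Zs
            if rho != 0.0:
                resp = resp - rho * prev
        p0 = np.full(p, prior.coefficient_precision)
        p0[K + 5:K + 5 + I] = tau_year
        Q = tau * (Z.T @ Z)
        Q[np.diag_indices_from(Q)] += p0
        L = cholesky(Q, lower=True)
        mean = cho_solve((L, True), tau * (Z.T @ resp))
        theta = mean + solve_triangular(L.T, rng.standard_normal(p), lower=False)
        if estimate_rho:
            rho = theta[-1]

        # --- precisions: conjugate Gamma draws ---
        resid = resp - Z @ theta
        ss = float(resid @ resid)
        tau = rng.gamma(a0 + 0.5 * n_tr, 1.0 / (b0 + 0.5 * ss))
        ye = theta[K + 5:K + 5 + I]
        tau_year = min(rng.gamma(a0 + 0.5 * I, 1.0 / (b0 + 0.5 * float(ye @ ye))), 1e12)

        if not adapting and (it - n_burnin + 1) % thin == 0:
            for k, s in enumerate(md.sites):
                out[f"site_{s}"][kept] = theta[k]
            for j, b in enumerate(BETA_NAMES):
                out[f"beta_{b}"][kept] = theta[K + j]
            for j, yr in enumerate(md.years):
                out[f"year_{yr}"][kept] = theta[K + 5 + j]
            if estimate_rho:
                out["rho"][kept] = rho
            out["sigma_process"][kept] = tau ** -0.5
            out["sigma_year"][kept] = tau_year ** -0.5
            if store_latent:
                latents[kept] = logN
            kept += 1

    accept_rate = acc_sum / max(acc_n, 1)
    return out, latents, accept_rate


class GobblingStateSpaceModel(BaseEstimator):
    """Scikit-learn style estimator for the gobbling state-space model.

    Parameters
    ----------
    estimate_rho
        Estimate the coefficient on lagged log-abundance (default); when
        False, ``rho_fixed`` is used (0 gives a covariate-driven random
        walk).
    n_chains, n_burnin, n_iterations, thin
        MCMC run lengths; defaults follow the 3-chain, 2,500 burn-in,
        10,000-iteration, thin-10 configuration.
    priors
        :class:`PriorSpec`; defaults are the vague priors above.
    store_latent
        Keep thinned latent trajectories (needed for trajectory
        prediction; off saves memory in simulation studies).
    random_state
        Seed; identical seeds give bit-identical chains.

    Attributes (after :meth:`fit`)
    ------------------------------
    chains_ : dict of parameter name -> (n_chains, n_kept) draws
    summary_ : posterior table (mean, sd, 2.5%, 97.5%, r_hat)
    rhat_ : dict of parameter name -> Gelman-Rubin statistic
    latent_chains_ : (n_chains, n_kept, S, T) latent draws, if stored
    accept_rate_ : mean post-burn-in Metropolis acceptance of the states
    """

    def __init__(self, estimate_rho=True, rho_fixed=0.0, n_chains=3,
                 n_burnin=2500, n_iterations=10000, thin=10,
                 priors=None, store_latent=False, random_state=None):
        self.estimate_rho = estimate_rho
        self.rho_fixed = rho_fixed
        self.n_chains = n_chains
        self.n_burnin = n_burnin
        self.n_iterations = n_iterations
        self.thin = thin
        self.priors = priors
        self.store_latent = store_latent
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        """Sample the posterior given a tidy model frame.

        ``X`` needs columns ``site, year, day, count, units`` and the four
        scaled weather covariates plus ``rain``; pass ``y`` to override the
        ``count`` column with an aligned array.
        """
        frame = X.copy()
        if y is not None:
            frame["count"] = np.asarray(y)
        settings = McmcSettings(n_chains=self.n_chains, n_burnin=self.n_burnin,
                                n_iterations=self.n_iterations, thin=self.thin)
        prior = self.priors if self.priors is not None else PriorSpec()
        md = ModelData.from_frame(frame)
        master = np.random.SeedSequence(self.random_state)
        chain_seeds = master.spawn(settings.n_chains)
        chains, latents, acc = {}, [], []
        for c, seq in enumerate(chain_seeds):
            draws, lat, a = _run_chain(
                md, n_burnin=settings.n_burnin,
                n_iterations=settings.n_iterations, thin=settings.thin,
                prior=prior, rng=np.random.default_rng(seq),
                estimate_rho=self.estimate_rho, rho_fixed=self.rho_fixed,
                chain_jitter=0.1 * (c + 1) / settings.n_chains,
                store_latent=self.store_latent)
            for name, arr in draws.items():
                chains.setdefault(name, []).append(arr)
            latents.append(lat)
            acc.append(a)
        self.model_data_ = md
        self.priors_ = prior
        self.chains_ = {k: np.stack(v) for k, v in chains.items()}
        self.latent_chains_ = (np.stack(latents) if self.store_latent else None)
        self.accept_rate_ = float(np.mean(acc))
        self.rhat_ = {k: dx.gelman_rubin(v) for k, v in self.chains_.items()}
        self.summary_ = dx.posterior_table(self.chains_)
        order = ([f"site_{s}" for s in md.sites]
                 + [f"beta_{b}" for b in BETA_NAMES]
                 + [f"year_{yr}" for yr in md.years]
                 + (["rho"] if self.estimate_rho else [])
                 + ["sigma_process", "sigma_year"])
        self.summary_ = self.summary_.loc[order]
        return self

    def summary_table(self, include_extras: bool = False) -> pd.DataFrame:
        """Posterior table in the conventional ordering: site intercepts,
        weather coefficients, year effects (plus rho and the variance
        components when ``include_extras``)."""
        md = self.model_data_
        order = ([f"site_{s}" for s in md.sites]
                 + [f"beta_{b}" for b in BETA_NAMES]
                 + [f"year_{yr}" for yr in md.years])
        if include_extras:
            order += (["rho"] if self.estimate_rho else []) + \
                ["sigma_process", "sigma_year"]
        return self.summary_.loc[order]

    def pooled_draws(self, name: str) -> np.ndarray:
        return self.chains_[name].reshape(-1)

    def converged(self, threshold: float = 1.1) -> bool:
        """Gelman-Rubin verdict: every monitored parameter below threshold."""
        return all(r < threshold for r in self.rhat_.values() if np.isfinite(r))

    def latent_draws(self, site, year) -> np.ndarray:
        """Pooled latent log-abundance draws, shape (n_draws, T)."""
        if self.latent_chains_ is None:
            raise ValueError("fit with store_latent=True to keep latent draws")
        s = self.model_data_.series_keys.index((site, year))
        T = self.model_data_.lengths[s]
        return self.latent_chains_[:, :, s, :T].reshape(-1, T)


def sample_posterior(frame: pd.DataFrame, priors: PriorSpec | None = None,
                     settings: McmcSettings | None = None,
                     **kwargs) -> GobblingStateSpaceModel:
    """Functional wrapper: fit the state-space model and return it."""
    settings = settings or McmcSettings()
    return GobblingStateSpaceModel(
        n_chains=settings.n_chains, n_burnin=settings.n_burnin,
        n_iterations=settings.n_iterations, thin=settings.thin,
        priors=priors, random_state=settings.seed, **kwargs,
    ).fit(frame)
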
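"""Convergence diagnostics, posterior summaries and effect displays.

Gelman-Rubin here is the classic potential scale reduction factor — the
ratio of the pooled-variance estimate ((n-1)/n W + B/n) to the mean
within-chain variance, square-rooted — with an optional split-chain
variant.  Posterior tables report mean, SD, and the empirical 2.5% and
97.5% quantiles (median-unbiased rule by default, configurable since
printed credible intervals cannot adjudicate the quantile convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QUANTILE_METHOD = "median_unbiased"


def gelman_rubin(chains, split: bool = False) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  Returns
    NaN (degenerate) when the within-chain variance is zero.  With
    ``split=True`` each chain is halved first, which also flags trending
    single chains.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array")
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 chains for the Gelman-Rubin statistic")
    if split:
        half = arr.shape[1] // 2
        arr = np.concatenate([arr[:, :half], arr[:, half:2 * half]], axis=0)
    m, n = arr.shape
    if n < 10:
        raise ValueError("need >= 10 draws per chain")
    within = arr.var(axis=1, ddof=1)
    W = within.mean()
    if W <= 0:
        return np.nan  # degenerate: constant chains
    B_over_n = arr.mean(axis=1).var(ddof=1)  # = B/n
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin_table(chains: dict, split: bool = False) -> pd.Series:
    return pd.Series({k: gelman_rubin(v, split=split) for k, v in chains.items()},
                     name="r_hat")


def posterior_table(chains: dict, quantile_method: str = QUANTILE_METHOD) -> pd.DataFrame:
    """Per-parameter posterior summary: mean, SD, 2.5%, 97.5%, r_hat.

    Chains are pooled (they are assumed post burn-in); the Gelman-Rubin
    column is computed per parameter before pooling.
    """
    rows = {}
    for name, draws in chains.items():
        arr = np.asarray(draws, dtype=float)
        pooled = arr.reshape(-1)
        q_lo, q_hi = np.quantile(pooled, [0.025, 0.975], method=quantile_method)
        rows[name] = {
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1),
            "q2.5": q_lo,
            "q97.5": q_hi,
            "r_hat": gelman_rubin(arr) if arr.ndim == 2 and arr.shape[0] >= 2 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def predict_trajectory(model, site, year, kind: str = "predictive",
                       seed=None) -> pd.DataFrame:
    """Pointwise posterior bands for one site-year's daily activity.

    ``kind="expected"`` summarizes the posterior of the expected count
    N_t = exp(logN_t); ``kind="predictive"`` additionally draws Poisson
    counts per retained draw (the posterior predictive of observations —
    the band observed counts should fall inside ~95% of the time).
    Returns day, observed, median, lo, hi, and band membership; the
    attribute ``coverage`` on the frame gives the fraction of observed
    days inside the band.
    """
    md = model.model_data_
    if (site, year) not in md.series_keys:
        raise ValueError(f"site-year ({site}, {year}) was not in the fit")
    s = md.series_keys.index((site, year))
    T = md.lengths[s]
    log_n = model.latent_draws(site, year)
    lam = np.exp(log_n)
    if kind == "expected":
        draws = lam
    elif kind == "predictive":
        rng = np.random.default_rng(seed)
        draws = rng.poisson(lam).astype(float)
    else:
        raise ValueError("kind must be 'expected' or 'predictive'")
    med = np.median(draws, axis=0)
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0, method=QUANTILE_METHOD)
    obs = md.y[s, :T]
    out = pd.DataFrame({
        "site": site, "year": year, "day": np.arange(1, T + 1),
        "observed": obs, "median": med, "lo": lo, "hi": hi,
    })
    inside = (obs >= lo) & (obs <= hi) & np.isfinite(obs)
    out["inside"] = inside
    n_obs = np.isfinite(obs).sum()
    out.attrs["coverage"] = float(inside.sum() / n_obs) if n_obs else np.nan
    return out


def effect_curve(beta_draws, grid, scale_mean: float = 0.0, scale_sd: float = 1.0,
                 baseline: float = 20.0) -> pd.DataFrame:
    """Expected gobbles across a covariate grid on its natural scale.

    Per draw b the curve is ``baseline * exp(b * (x - mean)/sd)``; for a
    binary covariate pass ``scale_mean=0, scale_sd=1`` and a {0, 1} grid.
    At the covariate mean the scaled value is 0, so every draw passes
    through the baseline exactly.  Returns grid, median and 95% CrI.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    if scale_sd <= 0:
        raise ValueError("scale_sd must be > 0")
    b = np.asarray(beta_draws, dtype=float).reshape(-1)
    grid = np.asarray(grid, dtype=float)
    scaled = (grid - scale_mean) / scale_sd
    curves = baseline * np.exp(np.outer(b, scaled))
    med = np.median(curves, axis=0)
    lo, hi = np.quantile(curves, [0.025, 0.975], axis=0, method=QUANTILE_METHOD)
    return pd.DataFrame({"grid": grid, "scaled": scaled,
                         "median": med, "lo": lo, "hi": hi})


def rain_contrast(beta_draws, baseline: float = 21.0) -> dict:
    """Expected gobbles with vs without rain from precipitation draws.

    The no-rain expectation is the baseline itself; the with-rain value is
    the posterior median of baseline*exp(beta).  Values are also given as
    nearest whole gobbles.
    """
    curve = effect_curve(beta_draws, [0.0, 1.0], 0.0, 1.0, baseline)
    dry, wet = curve["median"].to_numpy()
    return {"dry": float(dry), "wet": float(wet),
            "dry_rounded": int(round(dry)), "wet_rounded": int(round(wet)),
            "wet_lo": float(curve["lo"].iloc[1]), "wet_hi": float(curve["hi"].iloc[1])}


def recovery_report(truth: dict, chains: dict) -> pd.DataFrame:
    """Per-parameter recovery of known simulation truth.

    ``truth`` maps parameter names to true values; every named parameter
    must be present in ``chains``.  Reports posterior mean minus truth
    (bias), whether truth lies inside the central 95% credible interval,
    and the posterior RMSE around truth.
    """
    missing = set(truth) - set(chains)
    if missing:
        raise ValueError(f"parameters missing from chains: {sorted(missing)}")
    rows = {}
    for name, true_val in truth.items():
        pooled = np.asarray(chains[name], dtype=float).reshape(-1)
        lo, hi = np.quantile(pooled, [0.025, 0.975], method=QUANTILE_METHOD)
        rows[name] = {
            "truth": true_val,
            "posterior_mean": pooled.mean(),
            "bias": pooled.mean() - true_val,
            "covered": bool(lo <= true_val <= hi),
            "rmse": float(np.sqrt(np.mean((pooled - true_val) ** 2))),
            "q2.5": lo, "q97.5": hi,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def plot_trajectory(traj: pd.DataFrame, ax=None):
    """Render a predicted-vs-observed daily activity panel (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(traj["day"], traj["lo"], traj["hi"], color="0.8",
                    label="95% CrI")
    ax.plot(traj["day"], traj["median"], "k:", label="predicted")
    ax.plot(traj["day"], traj["observed"], "r-", lw=1, label="observed")
    ax.set_xlabel("day of season")
    ax.set_ylabel("gobbles")
    ax.legend(frameon=False)
    return ax
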
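"""Daily gobble counts and season summaries from verified detections.

Verified detection records (one row per candidate call, flagged true
gobble or false positive) become the daily count series the state-space
model consumes, with per-day recording effort carried alongside.  Season
summaries reproduce the standard survey table: detections, true gobbles,
percent true, and gobbles per recording unit, plus across-year site means
and percent differences between sites.

Display conventions: percent-true and percent-difference columns round to
whole percent; the integer site-level mean ± SD display columns truncate
toward zero.  Exact float values are always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SiteYearSummary:
    site: object
    year: int
    detections: int
    gobbles: int
    pct_true: int | None          # rounded whole percent; None if no detections
    gobbles_per_aru: float        # gobbles / effective units, 2 decimals


def daily_counts(records: pd.DataFrame, season_start, season_end,
                 units=1) -> pd.DataFrame:
    """Daily true-gobble counts over a site-year season.

    Parameters
    ----------
    records
        Detection rows with ``timestamp`` and ``verified`` (boolean or the
        strings ``true_gobble``/``false_positive``).  False positives
        contribute nothing; a record outside the season raises, naming it.
    season_start, season_end
        Inclusive calendar bounds of the season.
    units
        Per-day effort (number of units recording): scalar or length-T
        array.

    Returns one row per season day: ``day`` (1..T), ``date``, ``count``,
    ``units``.
    """
    start = pd.Timestamp(season_start).normalize()
    end = pd.Timestamp(season_end).normalize()
    days = pd.date_range(start, end, freq="D")
    T = len(days)
    u = np.broadcast_to(np.asarray(units), (T,))
    counts = np.zeros(T, dtype=int)
    if len(records):
        ts = pd.to_datetime(records["timestamp"])
        v = records["verified"]
        if v.dtype == object:
            truth = v.astype(str).str.lower().isin(("true_gobble", "true", "1"))
        else:
            truth = v.astype(bool)
        outside = (ts.dt.normalize() < start) | (ts.dt.normalize() > end)
        if outside.any():
            bad = records.loc[outside].iloc[0]
            raise ValueError(
                f"detection record at {bad['timestamp']} is outside the "
                f"season [{start.date()}, {end.date()}]"
            )
        day_idx = (ts.dt.normalize() - start).dt.days.to_numpy()
        np.add.at(counts, day_idx[truth.to_numpy()], 1)
    return pd.DataFrame({"day": np.arange(1, T + 1), "date": days,
                         "count": counts, "units": u})


def site_year_summary(detections: int, gobbles: int, n_units: int,
                      site=None, year=None) -> SiteYearSummary:
    """Season totals for one site-year.

    ``pct_true`` is the verified fraction as a rounded whole percent
    (undefined when there are no detections); ``gobbles_per_aru`` divides
    by the season-level effective unit count, kept at 2 decimals.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if gobbles > detections:
        raise ValueError("gobbles cannot exceed detections")
    pct = round(100.0 * gobbles / detections) if detections > 0 else None
    return SiteYearSummary(
        site=site, year=year, detections=int(detections), gobbles=int(gobbles),
        pct_true=pct, gobbles_per_aru=round(gobbles / n_units, 2),
    )


def summarize_seasons(rows: pd.DataFrame) -> pd.DataFrame:
    """Vectorized season summary table from ``site, year, detections,
    gobbles, units`` rows (the survey-table shape)."""
    out = rows.copy()
    out["pct_true"] = [
        site_year_summary(d, g, u).pct_true
        for d, g, u in zip(out["detections"], out["gobbles"], out["units"])
    ]
    out["gobbles_per_aru"] = [
        site_year_summary(d, g, u).gobbles_per_aru
        for d, g, u in zip(out["detections"], out["gobbles"], out["units"])
    ]
    return out


def overall_totals(rows: pd.DataFrame) -> dict:
    """Grand totals and the overall verified percentage."""
    det = int(rows["detections"].sum())
    gob = int(rows["gobbles"].sum())
    return {"detections": det, "gobbles": gob,
            "pct_true": round(100.0 * gob / det) if det else None}


def per_aru_stats(summaries: pd.DataFrame) -> pd.DataFrame:
    """Across-year site statistics of gobbles per recording unit.

    For each site: mean and sample SD (n-1 denominator; flagged
    unavailable for single-year sites) of the per-unit season totals, and
    the percent difference of the site mean below the best site's mean,
    rounded to a whole percent.  ``mean_int``/``sd_int`` are the truncated
    integer display columns.
    """
    if "gobbles_per_aru" not in summaries.columns:
        summaries = summarize_seasons(summaries)
    recs = []
    for site, grp in summaries.groupby("site", sort=False):
        vals = grp["gobbles_per_aru"].to_numpy(dtype=float)
        mean = float(vals.mean())
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else np.nan
        recs.append({"site": site, "n_years": len(vals), "mean": mean, "sd": sd})
    out = pd.DataFrame(recs)
    best = out["mean"].max()
    out["pct_below_max"] = [round(100.0 * (1.0 - m / best)) for m in out["mean"]]
    out["mean_int"] = [math.trunc(m) for m in out["mean"]]
    out["sd_int"] = [math.trunc(s) if np.isfinite(s) else None for s in out["sd"]]
    return out
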
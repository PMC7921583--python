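"""Rainfall effects on catches and cone seed retention.

Spruce cone scales close in damp weather, cutting off the seed supply, so
catches at garden feeders are expected to spike after rain.  The analysis is
deliberately simple and robust across seasons: a Pearson correlation between
per-session adult counts and the rainfall total over the three preceding
days, computed within each season's period of abundance, followed by an
exact one-sided sign test of how many seasons came out positive.

Seed retention in cones is measured by dissection: each cone scale holds two
seeds when full, so a cone with ``n_scales`` scales held at most
``2 * n_scales`` seeds, and the extracted count over that maximum is the
retention percentage.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "antecedent_rainfall",
    "abundance_period",
    "within_year_rain_correlation",
    "cross_year_sign_test",
    "seed_retention_percent",
    "retention_curve",
]


def antecedent_rainfall(series: pd.Series, session_date, window: int = 3) -> float:
    """Total rainfall (mm) over the ``window`` days strictly before a session.

    ``series`` maps daily dates to mm.  A missing day inside the window is an
    error naming the date — no silent imputation.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    day = pd.Timestamp(session_date)
    total = 0.0
    idx = pd.DatetimeIndex(series.index)
    for k in range(1, window + 1):
        d = day - pd.Timedelta(days=k)
        if d not in idx:
            raise KeyError(f"rainfall series has no entry for {d.date()}")
        val = series.loc[d]
        total += float(val)
    return total


@dataclass(frozen=True)
class AbundancePeriod:
    """Within-season span of consistently high catches: from the first to the
    last session with at least ``frac`` of the season's maximum adult count."""

    start: pd.Timestamp
    end: pd.Timestamp
    n_sessions: int


def abundance_period(season_sessions: pd.DataFrame, frac: float = 0.2) -> AbundancePeriod | None:
    """Period of abundance for one season's session summaries."""
    s = season_sessions.sort_values("session_date")
    peak = s["n_adults"].max()
    if not peak or peak <= 0:
        return None
    hot = s.loc[s["n_adults"] >= frac * peak, "session_date"]
    start, end = hot.iloc[0], hot.iloc[-1]
    inside = s.loc[(s["session_date"] >= start) & (s["session_date"] <= end)]
    return AbundancePeriod(start=start, end=end, n_sessions=len(inside))


def within_year_rain_correlation(
    sessions: pd.DataFrame,
    rainfall: pd.Series,
    window: int = 3,
    frac: float = 0.2,
) -> pd.DataFrame:
    """Pearson r of adult count vs antecedent rainfall, per cone year.

    Sessions outside the season's period of abundance are excluded so that
    the correlation is not driven by the arrival ramp and late-season fade.
    Returns one row per cone year with ``r``, two-sided ``p``, ``n`` and a
    ``defined`` flag (False on < 3 usable sessions or zero variance).
    """
    rows = []
    for year, grp in sessions.groupby("cone_year"):
        period = abundance_period(grp, frac=frac)
        row = {"cone_year": int(year), "r": np.nan, "p": np.nan, "n": 0,
               "defined": False}
        if period is not None:
            g = grp.loc[
                (grp["session_date"] >= period.start)
                & (grp["session_date"] <= period.end)
            ]
            rain = np.array(
                [antecedent_rainfall(rainfall, d, window) for d in g["session_date"]]
            )
            counts = g["n_adults"].to_numpy(dtype=float)
            row["n"] = int(counts.size)
            if counts.size >= 3 and np.ptp(counts) > 0 and np.ptp(rain) > 0:
                r, p = stats.pearsonr(counts, rain)
                row.update(r=float(r), p=float(p), defined=True)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("cone_year").reset_index(drop=True)


def cross_year_sign_test(r_values) -> float:
    """Exact one-sided binomial p for "positive rather than negative trend".

    With ``k`` positive correlations out of ``n`` nonzero ones, the tail
    P(X ≥ k | n, 1/2) is summed directly over binomial coefficients; exact
    zeros (and NaNs) are dropped as ties.
    """
    r = np.asarray(list(r_values), dtype=float)
    r = r[np.isfinite(r) & (r != 0)]
    n = r.size
    if n == 0:
        raise ValueError("no signed correlations to test")
    k = int((r > 0).sum())
    return float(sum(comb(n, i) for i in range(k, n + 1)) / 2**n)


def seed_retention_percent(n_scales: int, n_seeds_extracted: int) -> float:
    """Seeds extracted as a percentage of the cone's maximum (2 per scale)."""
    if n_scales <= 0:
        raise ValueError("a cone must have a positive number of scales")
    if n_seeds_extracted < 0 or n_seeds_extracted > 2 * n_scales:
        raise ValueError(
            f"{n_seeds_extracted} seeds from {n_scales} scales exceeds the "
            f"2-per-scale maximum"
        )
    return 100.0 * n_seeds_extracted / (2.0 * n_scales)


def retention_curve(samples: pd.DataFrame, site: str) -> pd.DataFrame:
    """Monthly mean seed-retention percentage for one collection site.

    ``samples`` has columns ``site``, ``collection_date``, ``n_scales``,
    ``n_seeds_extracted``.  Returns per-month mean, standard deviation and n,
    plus a ``monotone_decreasing`` diagnostic on the means (reported, not
    enforced — retention should only fall as seeds shed).
    """
    df = samples.loc[samples["site"] == site].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["month", "mean_retention", "sd_retention", "n"]
        )
    df["retention"] = [
        seed_retention_percent(a, b)
        for a, b in zip(df["n_scales"], df["n_seeds_extracted"])
    ]
    df["month"] = pd.to_datetime(df["collection_date"]).dt.to_period("M")
    out = (
        df.groupby("month")["retention"]
        .agg(mean_retention="mean", sd_retention="std", n="size")
        .reset_index()
        .sort_values("month")
        .reset_index(drop=True)
    )
    out.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(out["mean_retention"]) <= 1e-9)
    )
    return out
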
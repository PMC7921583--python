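"""Season-level phenology metrics and their cone-score regressions.

Two direct timing metrics are computed per season: the arrival date of
adults (first capture, expressed as days after 31 Oct) and the day of year
by which half of the adult females carry a well-formed brood patch — the
classic index that incubation has begun.  Each is regressed across seasons
on the autumn cone-crop score; in a masting-driven system both slopes are
expected to be negative (earlier in big crop years).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regression import RegressionResult, simple_ols
from .ringing import ADULT_AGE_CODES

__all__ = [
    "BroodPatchMidpoint",
    "brood_patch_midpoint",
    "arrival_vs_cone_regression",
    "brood_patch_vs_cone_regression",
]


@dataclass(frozen=True)
class BroodPatchMidpoint:
    """Day of year at which the fitted probability of a well-formed brood
    patch reaches 0.5; ``defined`` is False when the responses carry no
    information about a rising phase (all one class, or a decreasing fit)."""

    defined: bool
    day: float | None = None
    slope_per_day: float | None = None
    n: int = 0
    method: str = "logistic_mle"


def brood_patch_midpoint(
    female_adult_records: pd.DataFrame,
    well_formed_threshold: int = 3,
    ascending_cutoff_day: int = 181,
) -> BroodPatchMidpoint:
    """Logistic 50% day for brood-patch presence on adult females.

    Only the ascending phase (day of year ≤ ``ascending_cutoff_day``,
    default = 30 June) enters the fit, because patches re-feather after
    breeding and the raw proportion is non-monotone over the full season.
    A patch is "well formed" at score ≥ ``well_formed_threshold`` on the 0–5
    scale.  Perfectly separated responses (all zeros strictly before all
    ones) pin the midpoint only to the gap between the last bare and first
    patched day; the gap midpoint is returned, flagged ``method="separation"``.
    """
    df = female_adult_records.dropna(subset=["brood_patch"]).copy()
    if "day_of_year" not in df.columns:
        df["day_of_year"] = pd.to_datetime(df["session_date"]).dt.dayofyear
    df = df.loc[df["day_of_year"] <= ascending_cutoff_day]
    if df.empty:
        return BroodPatchMidpoint(defined=False)
    t = df["day_of_year"].to_numpy(dtype=float)
    y = (df["brood_patch"].to_numpy(dtype=float) >= well_formed_threshold).astype(float)

    if y.min() == y.max():
        return BroodPatchMidpoint(defined=False, n=t.size)
    t0_max, t1_min = t[y == 0].max(), t[y == 1].min()
    if t0_max < t1_min:  # complete separation: MLE diverges, midpoint does not
        return BroodPatchMidpoint(
            defined=True, day=float((t0_max + t1_min) / 2.0),
            slope_per_day=np.inf, n=t.size, method="separation",
        )

    X = sm.add_constant(t)
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    b0, b1 = fit.params
    if not np.isfinite(b1) or b1 <= 0:
        return BroodPatchMidpoint(defined=False, n=t.size)
    return BroodPatchMidpoint(
        defined=True, day=float(-b0 / b1), slope_per_day=float(b1), n=t.size
    )


def female_adult_subset(records: pd.DataFrame, species: str) -> pd.DataFrame:
    """Adult females of the focal species, the brood-patch denominator."""
    m = (
        (records["species"] == species)
        & (records["sex"] == "F")
        & records["euring_age"].isin(ADULT_AGE_CODES)
    )
    return records.loc[m].copy()


def arrival_vs_cone_regression(seasons: pd.DataFrame) -> RegressionResult:
    """OLS of arrival offset (days after 31 Oct) on cone score.

    ``seasons`` needs columns ``cone_score`` and ``arrival_offset``; seasons
    with undefined arrival are dropped.  The slope is in days per score
    point, negative when birds return earlier after a big mast.
    """
    d = seasons.dropna(subset=["arrival_offset", "cone_score"])
    return simple_ols(d["cone_score"], d["arrival_offset"], term="cone_score")


def brood_patch_vs_cone_regression(seasons: pd.DataFrame) -> RegressionResult:
    """OLS of the brood-patch 50% day of year on cone score."""
    d = seasons.dropna(subset=["brood_patch_midpoint", "cone_score"])
    return simple_ols(d["cone_score"], d["brood_patch_midpoint"], term="cone_score")
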
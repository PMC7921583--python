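"""Demographic responses to the cone crop.

Covers breeding output (the June–July fledgling proportion, locally and in a
supplied national ringing-totals table), adult abundance (cone score with a
calendar-year covariate, since background abundance drifts across a long
study), juvenile condition (monthly mean mass and wing vs cone score), and
the carry-over test of whether a big crop leaves a mark on next season's
adult age structure (first-year proportion vs previous autumn's score).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .regression import RegressionResult, additive_ols, simple_ols
from .ringing import ADULT_AGE_CODES, FIRST_YEAR_ADULT_CODE

__all__ = [
    "junejuly_fledgling_proportion",
    "junejuly_vs_cone_regression",
    "adult_abundance_model",
    "juvenile_condition_model",
    "carryover_age_ratio",
    "national_juvenile_regression",
]


def junejuly_fledgling_proportion(records: pd.DataFrame, species: str) -> pd.DataFrame:
    """Fledglings as a proportion of all aged birds caught in June–July.

    Computed per cone year at the peak of the breeding season (calendar June
    and July).  Rows with a zero denominator carry NaN and ``defined=False``.
    """
    df = records.loc[records["species"] == species].copy()
    dates = pd.to_datetime(df["session_date"])
    df = df.loc[dates.dt.month.isin([6, 7])]
    dates = pd.to_datetime(df["session_date"])
    df["cone_year"] = dates.dt.year.where(dates.dt.month >= 10, dates.dt.year - 1)
    adult = df["euring_age"].isin(ADULT_AGE_CODES)
    fledg = df["fledgling"].astype(bool)
    aged = adult | fledg | df["euring_age"].isin([1, 3])
    out = (
        df.assign(_fl=fledg, _aged=aged)
        .groupby("cone_year")[["_fl", "_aged"]]
        .sum()
        .reset_index()
        .rename(columns={"_fl": "n_fledglings", "_aged": "n_aged"})
    )
    out["proportion"] = out["n_fledglings"] / out["n_aged"].replace(0, np.nan)
    out["defined"] = out["n_aged"] > 0
    return out


def junejuly_vs_cone_regression(
    proportions: pd.DataFrame, cone_scores: pd.DataFrame
) -> RegressionResult:
    """OLS of the June–July fledgling proportion on cone score."""
    merged = proportions.loc[proportions["defined"]].merge(cone_scores, on="cone_year")
    return simple_ols(merged["cone_score"], merged["proportion"], term="cone_score")


def adult_abundance_model(seasons: pd.DataFrame) -> RegressionResult:
    """Mean adults per catch ~ cone score + calendar year (both continuous).

    The year covariate absorbs the slow drift in background abundance over a
    multi-decade study so the cone-score term is tested against it.  Needs
    columns ``mean_adults``, ``cone_score``, ``cone_year`` and ≥ 4 seasons.
    """
    df = seasons.dropna(subset=["mean_adults", "cone_score", "cone_year"])
    if len(df) < 4:
        raise ValueError("need at least 4 seasons for the additive model")
    return additive_ols(
        df, response="mean_adults", focal="cone_score", covariates=("cone_year",)
    )


def juvenile_condition_model(
    records: pd.DataFrame,
    species: str,
    cone_scores: pd.DataFrame,
    measure: str = "mass_g",
    months: tuple[int, ...] = (5, 6, 7),
    min_captures: int = 10,
) -> RegressionResult:
    """Monthly mean juvenile size ~ month (categorical) + cone score.

    Monthly means of fledgling ``measure`` (mass or wing) are computed per
    season for the core months (May–July) and any season-month cell with
    fewer than ``min_captures`` measured birds is excluded as unreliable.
    The reported test is the cone-score term of the additive model.
    """
    df = records.loc[
        (records["species"] == species) & records["fledgling"].astype(bool)
    ].dropna(subset=[measure]).copy()
    dates = pd.to_datetime(df["session_date"])
    df["month"] = dates.dt.month
    df = df.loc[df["month"].isin(months)]
    df["cone_year"] = dates.dt.year.where(dates.dt.month >= 10, dates.dt.year - 1)
    cells = (
        df.groupby(["cone_year", "month"])[measure]
        .agg(value="mean", n="size")
        .reset_index()
    )
    cells = cells.loc[cells["n"] >= min_captures]
    if cells.empty:
        raise ValueError("every season-month cell fell below the capture minimum")
    cells = cells.merge(cone_scores, on="cone_year")
    return additive_ols(
        cells, response="value", focal="cone_score",
        covariates=("month",), categorical=("month",),
    )


def carryover_age_ratio(seasons: pd.DataFrame) -> RegressionResult:
    """First-year adult proportion vs the *previous* autumn's cone score.

    First-year adults (EURING 5) hatched during the previous season, so a
    productive crop then should — absent a winter bottleneck — inflate their
    share now.  ``seasons`` needs ``cone_year``, ``cone_score`` and
    ``first_year_proportion``; the previous score is looked up internally
    and seasons without one are dropped.
    """
    df = seasons.copy()
    prev = df[["cone_year", "cone_score"]].assign(cone_year=df["cone_year"] + 1)
    prev = prev.rename(columns={"cone_score": "prev_cone_score"})
    df = df.merge(prev, on="cone_year").dropna(
        subset=["first_year_proportion", "prev_cone_score"]
    )
    return simple_ols(
        df["prev_cone_score"], df["first_year_proportion"], term="prev_cone_score"
    )


def national_juvenile_regression(
    table: pd.DataFrame, cone_scores: pd.DataFrame
) -> RegressionResult:
    """Annual national juvenile proportion vs the local cone score.

    ``table`` has columns ``year``, ``juveniles``, ``total`` (ringing totals
    for the whole recording area); ringing years are matched to the cone
    crop of the previous autumn (``cone_year = year - 1``).  Years without a
    matching score raise an error listing them.
    """
    df = table.copy()
    df["cone_year"] = df["year"] - 1
    merged = df.merge(cone_scores, on="cone_year", how="left")
    missing = merged.loc[merged["cone_score"].isna(), "year"].tolist()
    if missing:
        raise ValueError(f"no cone score for ringing years: {missing}")
    merged["proportion"] = merged["juveniles"] / merged["total"]
    return simple_ols(merged["cone_score"], merged["proportion"], term="cone_score")
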
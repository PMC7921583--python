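"""Ringing-session data model: calendar conventions, aggregation and filtering.

Individual capture records (one bird handled in one mist-net session) are held
in a :class:`pandas.DataFrame` with the columns of :data:`CAPTURE_COLUMNS`.
Session-level analysis works on per-catch-day summaries produced by
:func:`aggregate_sessions`: counts by age/sex class and the composition ratios
(female proportion of sexed adults, fledgling proportion of aged birds,
first-year proportion of aged adults) that the phenology analyses use in place
of absolute numbers, so that variable netting effort and weather cancel out.

Two calendar conventions run through the whole package:

* day-of-year ``t`` is 1-based (1 Jan = 1), on the real calendar;
* each capture belongs to a *cone year*: the autumn crop that ripened
  immediately before it.  Dates from 1 Oct of year ``y`` through 30 Sep of
  year ``y + 1`` carry ``cone_year = y``, because a brood reared in spring
  ``y + 1`` was provisioned from the cones that ripened in autumn ``y``.
  Arrival dates are expressed as days after 31 Oct of the cone year.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CAPTURE_COLUMNS",
    "ADULT_AGE_CODES",
    "FIRST_YEAR_ADULT_CODE",
    "CaptureRecord",
    "day_offset_from_oct31",
    "assign_cone_year",
    "day_of_year",
    "aggregate_sessions",
    "filter_for_curve",
    "first_arrival",
    "FirstArrival",
]

#: Expected columns of a capture-record frame (see :mod:`mastphen.io`).
CAPTURE_COLUMNS = (
    "session_date",
    "species",
    "ring_id",
    "euring_age",
    "fledgling",
    "sex",
    "mass_g",
    "wing_mm",
    "brood_patch",
    "time_min",
)

#: EURING age codes counted as adult (4 = adult of unknown hatch year,
#: 5 = hatched previous calendar year, 6 = hatched before previous year).
ADULT_AGE_CODES = frozenset({4, 5, 6})
#: EURING code identifying a first-year adult.
FIRST_YEAR_ADULT_CODE = 5

VALID_AGE_CODES = frozenset({1, 3, 4, 5, 6})
VALID_SEXES = frozenset({"F", "M", "U"})


@dataclass(frozen=True)
class CaptureRecord:
    """One bird handled in one session.

    ``euring_age`` follows the EURING convention ({1, 3, 4, 5, 6} here);
    ``fledgling`` marks a juvenile caught before its post-juvenile moult —
    such a bird is never an adult.  ``brood_patch`` is the 0–5 incubation
    patch score taken on adult females, ``time_min`` minutes since midnight
    at 30-minute resolution.  Optional fields are ``None`` when missing.
    """

    session_date: date
    species: str
    ring_id: str
    euring_age: int
    fledgling: bool = False
    sex: str = "U"
    mass_g: float | None = None
    wing_mm: int | None = None
    brood_patch: int | None = None
    time_min: int | None = None

    def __post_init__(self) -> None:
        if self.euring_age not in VALID_AGE_CODES:
            raise ValueError(f"invalid EURING age code {self.euring_age!r}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"invalid sex code {self.sex!r}")
        if self.fledgling and self.euring_age in ADULT_AGE_CODES:
            raise ValueError("a fledgling cannot carry an adult age code")
        if self.mass_g is not None and not self.mass_g > 0:
            raise ValueError("mass must be positive when present")
        if self.wing_mm is not None and not self.wing_mm > 0:
            raise ValueError("wing length must be positive when present")
        if self.brood_patch is not None and not 0 <= self.brood_patch <= 5:
            raise ValueError("brood patch score must be in 0–5")


def day_offset_from_oct31(d: date | pd.Timestamp) -> int:
    """Days after 31 October of the season's reference year.

    31 Oct of the cone year maps to 0 and each following day adds 1, through
    the real calendar (leap days count).  Dates in Oct on/after the 1st but
    before the 31st belong to the same season and get negative offsets.
    """
    d = pd.Timestamp(d)
    ref_year = assign_cone_year(d)
    return (d - pd.Timestamp(year=ref_year, month=10, day=31)).days


def assign_cone_year(d: date | pd.Timestamp) -> int:
    """Season assignment: 1 Oct of year ``y`` … 30 Sep of ``y+1`` → ``y``."""
    d = pd.Timestamp(d)
    return d.year if d.month >= 10 else d.year - 1


def day_of_year(d: date | pd.Timestamp) -> int:
    """1-based day of the calendar year (1 Jan = 1)."""
    return pd.Timestamp(d).dayofyear


def _cone_year_vec(dates: pd.Series) -> pd.Series:
    dates = pd.to_datetime(dates)
    return dates.dt.year.where(dates.dt.month >= 10, dates.dt.year - 1)


def _check_session_conflicts(df: pd.DataFrame) -> None:
    """A ring read twice in one session must agree on identity fields."""
    ident = ["euring_age", "fledgling", "sex"]
    grp = df.groupby(["session_date", "ring_id"])[ident].nunique()
    bad = grp[(grp > 1).any(axis=1)]
    if len(bad):
        key = bad.index[0]
        raise ValueError(
            f"conflicting duplicate capture of ring {key[1]!r} on {key[0]}"
        )


def aggregate_sessions(records: pd.DataFrame, species: str) -> pd.DataFrame:
    """Collapse individual captures into per-catch-day summaries.

    Parameters
    ----------
    records
        Capture-record frame (columns as :data:`CAPTURE_COLUMNS`; extra
        columns are ignored).
    species
        Focal species code; other species contribute nothing to the counts.

    Returns
    -------
    DataFrame indexed 0..n with one row per distinct ``session_date``:
    counts (``n_total``, ``n_adults``, ``n_adult_female``, ``n_adult_male``,
    ``n_adult_first_year``, ``n_adult_aged``, ``n_fledglings``, ``n_aged``),
    calendar fields (``day_of_year``, ``cone_year``, ``oct31_offset``) and
    ratios (``sex_ratio``, ``fledgling_ratio``, ``first_year_ratio``), NaN
    where the denominator is zero.  Birds of unknown sex are excluded from
    the sexed denominator only; EURING code 4 counts as adult but never as
    first-year.
    """
    df = records.loc[records["species"] == species].copy()
    if df.empty:
        cols = [
            "session_date", "day_of_year", "cone_year", "oct31_offset",
            "n_total", "n_adults", "n_adult_female", "n_adult_male",
            "n_adult_first_year", "n_adult_aged", "n_fledglings", "n_aged",
            "sex_ratio", "fledgling_ratio", "first_year_ratio",
        ]
        return pd.DataFrame(columns=cols)
    _check_session_conflicts(df)

    df["session_date"] = pd.to_datetime(df["session_date"])
    adult = df["euring_age"].isin(ADULT_AGE_CODES)
    fledg = df["fledgling"].astype(bool)
    aged = adult | fledg | df["euring_age"].isin([1, 3])

    out = pd.DataFrame({"n_total": df.groupby("session_date").size()})
    agg = df.assign(
        _adult=adult,
        _af=adult & (df["sex"] == "F"),
        _am=adult & (df["sex"] == "M"),
        _a5=df["euring_age"] == FIRST_YEAR_ADULT_CODE,
        _a56=df["euring_age"].isin([5, 6]),
        _fl=fledg,
        _aged=aged,
    ).groupby("session_date")[["_adult", "_af", "_am", "_a5", "_a56", "_fl", "_aged"]].sum()
    out["n_adults"] = agg["_adult"]
    out["n_adult_female"] = agg["_af"]
    out["n_adult_male"] = agg["_am"]
    out["n_adult_first_year"] = agg["_a5"]
    out["n_adult_aged"] = agg["_a56"]
    out["n_fledglings"] = agg["_fl"]
    out["n_aged"] = agg["_aged"]
    out = out.reset_index().sort_values("session_date").reset_index(drop=True)

    out["day_of_year"] = out["session_date"].dt.dayofyear
    out["cone_year"] = _cone_year_vec(out["session_date"])
    ref = pd.to_datetime(
        {"year": out["cone_year"], "month": 10, "day": 31}
    )
    out["oct31_offset"] = (out["session_date"] - ref).dt.days

    sexed = out["n_adult_female"] + out["n_adult_male"]
    out["sex_ratio"] = out["n_adult_female"] / sexed.replace(0, np.nan)
    out["fledgling_ratio"] = out["n_fledglings"] / out["n_aged"].replace(0, np.nan)
    out["first_year_ratio"] = (
        out["n_adult_first_year"] / out["n_adult_aged"].replace(0, np.nan)
    )
    return out


_METRIC_DENOMS = {
    "sex_ratio": ("n_adult_female", "n_adult_male"),
    "fledgling_ratio": ("n_aged",),
}


def filter_for_curve(
    sessions: pd.DataFrame,
    metric: str,
    min_birds: int = 15,
    max_doy: int = 220,
) -> pd.DataFrame:
    """Session filter applied before fitting pooled composition curves.

    Keeps sessions on or before calendar day ``max_doy`` with at least
    ``min_birds`` *valid* birds, where valid means countable toward the
    metric's denominator: sexed adults for ``sex_ratio``, aged birds for
    ``fledgling_ratio``.  Small catches are dropped because their ratios can
    be extreme purely by sampling chance; late-season catches because the
    focal species is nearly absent then.  Idempotent and order-independent.
    """
    if metric not in _METRIC_DENOMS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_DENOMS)}")
    valid = sum(sessions[c] for c in _METRIC_DENOMS[metric])
    keep = (sessions["day_of_year"] <= max_doy) & (valid >= min_birds)
    return sessions.loc[keep].copy()


@dataclass(frozen=True)
class FirstArrival:
    """First session of the season with at least one adult of the focal
    species; ``defined`` is False when the species never appeared."""

    defined: bool
    date: pd.Timestamp | None = None
    oct31_offset: int | None = None


def first_arrival(season_sessions: pd.DataFrame) -> FirstArrival:
    """Arrival of the focal species in one season's session summaries."""
    if season_sessions.empty:
        return FirstArrival(defined=False)
    present = season_sessions.loc[season_sessions["n_adults"] >= 1]
    if present.empty:
        return FirstArrival(defined=False)
    row = present.sort_values("session_date").iloc[0]
    return FirstArrival(
        defined=True,
        date=row["session_date"],
        oct31_offset=int(row["oct31_offset"]),
    )
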
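"""CSV readers and writers for the study's input tables.

All tables are UTF-8 CSV with a header row and ISO-8601 dates.  Readers
validate codes and ranges and report the first offending row by line number
(header = line 1), rather than silently coercing; writers round mass to
0.01 g.  Schemas:

``captures.csv``
    session_date, species, ring_id, euring_age (1/3/4/5/6), fledgling (0/1),
    sex (F/M/U), mass_g, wing_mm, brood_patch (0–5, may be blank),
    time_hhmm or time_min (optional).
``rainfall.csv``    date, rain_mm (>= 0, daily, no duplicate dates).
``cone_scores.csv`` autumn_year, score (integer 0–10).
``isotopes.csv``    sample_id, species, cone_year, tissue (feather/seed),
                    d15N, d13C (per mil; sanity-bounded).
``cone_samples.csv`` site, collection_date, n_scales (> 0),
                    n_seeds_extracted (0 … 2×n_scales).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ringing import VALID_AGE_CODES, VALID_SEXES

__all__ = [
    "read_captures",
    "read_rainfall",
    "read_cone_scores",
    "read_isotopes",
    "read_cone_samples",
    "write_captures",
]

#: Configurable sanity bounds for isotope values (per mil).
D15N_BOUNDS = (-10.0, 20.0)
D13C_BOUNDS = (-35.0, -10.0)


class SchemaError(ValueError):
    """An input table violated its schema; the message names file and line."""


def _fail(path, idx, message) -> None:
    # +2: header line plus 1-based numbering
    raise SchemaError(f"{path}, line {int(idx) + 2}: {message}")


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_captures(path) -> pd.DataFrame:
    """Read and validate a capture-record table."""
    path = Path(path)
    df = pd.read_csv(path)
    _require(
        df,
        ["session_date", "species", "ring_id", "euring_age", "fledgling", "sex"],
        path,
    )
    df["session_date"] = pd.to_datetime(df["session_date"], format="ISO8601")
    bad = ~df["euring_age"].isin(list(VALID_AGE_CODES))
    if bad.any():
        i = df.index[bad][0]
        _fail(path, i, f"invalid EURING age code {df.loc[i, 'euring_age']!r}")
    df["sex"] = df["sex"].fillna("U")
    bad = ~df["sex"].isin(list(VALID_SEXES))
    if bad.any():
        i = df.index[bad][0]
        _fail(path, i, f"invalid sex code {df.loc[i, 'sex']!r}")
    df["fledgling"] = df["fledgling"].astype(int)
    adult = df["euring_age"].isin([4, 5, 6])
    clash = adult & (df["fledgling"] == 1)
    if clash.any():
        _fail(path, df.index[clash][0], "fledgling flag on an adult age code")
    for col, low in (("mass_g", 0.0), ("wing_mm", 0.0)):
        if col in df.columns:
            bad = df[col].notna() & (df[col] <= low)
            if bad.any():
                i = df.index[bad][0]
                _fail(path, i, f"nonpositive {col} {df.loc[i, col]!r}")
    if "brood_patch" in df.columns:
        bp = df["brood_patch"]
        bad = bp.notna() & ((bp < 0) | (bp > 5))
        if bad.any():
            i = df.index[bad][0]
            _fail(path, i, f"brood patch score {df.loc[i, 'brood_patch']!r} not in 0-5")
    else:
        df["brood_patch"] = np.nan
    if "time_hhmm" in df.columns and "time_min" not in df.columns:
        hhmm = pd.to_datetime(df["time_hhmm"], format="%H:%M", errors="coerce")
        df["time_min"] = hhmm.dt.hour * 60 + hhmm.dt.minute
    return df


def read_rainfall(path) -> pd.Series:
    """Daily rainfall as a date-indexed series (mm); gaps are the caller's
    concern but duplicates and negative amounts are rejected here."""
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["date", "rain_mm"], path)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    dup = df["date"].duplicated()
    if dup.any():
        i = df.index[dup][0]
        _fail(path, i, f"duplicate date {df.loc[i, 'date'].date()}")
    neg = df["rain_mm"] < 0
    if neg.any():
        i = df.index[neg][0]
        _fail(path, i, f"negative rainfall {df.loc[i, 'rain_mm']!r}")
    return df.set_index("date")["rain_mm"].sort_index()


def read_cone_scores(path) -> pd.DataFrame:
    """Autumn cone-crop scores, one integer 0–10 per autumn year.

    Returns columns ``cone_year`` and ``cone_score`` as used downstream.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["autumn_year", "score"], path)
    bad = (df["score"] < 0) | (df["score"] > 10) | (df["score"] != df["score"].astype(int))
    if bad.any():
        i = df.index[bad][0]
        _fail(path, i, f"cone score {df.loc[i, 'score']!r} not an integer in 0-10")
    return df.rename(columns={"autumn_year": "cone_year", "score": "cone_score"})[
        ["cone_year", "cone_score"]
    ]


def read_isotopes(path) -> pd.DataFrame:
    """Feather and seed isotope samples with sanity-bounded values."""
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["sample_id", "species", "cone_year", "tissue", "d15N", "d13C"], path)
    bad = ~df["tissue"].isin(["feather", "seed"])
    if bad.any():
        i = df.index[bad][0]
        _fail(path, i, f"tissue {df.loc[i, 'tissue']!r} not feather/seed")
    for col, (lo, hi) in (("d15N", D15N_BOUNDS), ("d13C", D13C_BOUNDS)):
        bad = (df[col] < lo) | (df[col] > hi)
        if bad.any():
            i = df.index[bad][0]
            _fail(path, i, f"{col} = {df.loc[i, col]} outside sanity bounds {lo}..{hi}")
    return df


def read_cone_samples(path) -> pd.DataFrame:
    """Cone dissection samples (site, date, scales, seeds extracted)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require(df, ["site", "collection_date", "n_scales", "n_seeds_extracted"], path)
    df["collection_date"] = pd.to_datetime(df["collection_date"], format="ISO8601")
    bad = df["n_scales"] <= 0
    if bad.any():
        _fail(path, df.index[bad][0], "cone with no scales")
    bad = (df["n_seeds_extracted"] < 0) | (
        df["n_seeds_extracted"] > 2 * df["n_scales"]
    )
    if bad.any():
        i = df.index[bad][0]
        _fail(
            path, i,
            f"{df.loc[i, 'n_seeds_extracted']} seeds exceeds 2 x "
            f"{df.loc[i, 'n_scales']} scales",
        )
    return df


def write_captures(df: pd.DataFrame, path) -> None:
    """Write capture records; mass rounded to 0.01 g."""
    out = df.copy()
    if "mass_g" in out.columns:
        out["mass_g"] = out["mass_g"].round(2)
    out.to_csv(path, index=False)
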
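"""Small published data tables bundled with the package.

:func:`load_season_summary` returns the printed per-season summary of the
2005–2020 Argyll mist-netting study: autumn cone-crop score, netting effort,
total siskins, first-arrival date, the period of consistently high catches,
the within-season rain–catch correlation and the mean adults per catch.
These are the day-rounded printed values, not the raw capture records, so
statistics recomputed from them can differ slightly from analyses of the
underlying data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ringing import day_offset_from_oct31

__all__ = ["load_season_summary", "FEATHER_SAMPLES_PER_YEAR"]

#: Number of fledgling siskin feather samples analysed per sampling year.
FEATHER_SAMPLES_PER_YEAR = {
    2001: 6,
    2007: 10,
    2009: 10,
    2011: 10,
    2016: 10,
    2017: 10,
    2018: 10,
    2019: 10,
    2020: 10,
}


def load_season_summary() -> pd.DataFrame:
    """Per-season summary table of the Argyll study (16 cone years).

    Adds ``arrival_offset`` (days after 31 Oct of the cone year) computed
    from the printed arrival dates.
    """
    ref = resources.files("mastphen.data") / "argyll_season_summary.csv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(
            path, parse_dates=["arrival_date", "abundance_start", "abundance_end"]
        )
    df["arrival_offset"] = [day_offset_from_oct31(d) for d in df["arrival_date"]]
    return df
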
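"""Full-pipeline driver: one call from the five input tables to every
cross-season statistic, a season summary table, and a machine-readable
report.

:func:`run_all` mirrors the structure of the study's results: arrival and
brood-patch phenology, curve registration of the sex-ratio and fledgling
curves, rainfall correlations with the cross-year sign test, the isotope
diet analyses, and the demographic models.  Every number in the
human-readable season table also appears in the JSON dict, and a
:class:`RunManifest` records input digests, seed, version and per-stage
timings so a run can be reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .demography import (
    adult_abundance_model,
    carryover_age_ratio,
    junejuly_fledgling_proportion,
    junejuly_vs_cone_regression,
    juvenile_condition_model,
)
from .environment import (
    abundance_period,
    cross_year_sign_test,
    within_year_rain_correlation,
)
from .isotopes import (
    HIGH_CROP_SCORE,
    DietExpectation,
    isotope_vs_cone_regression,
    seed_diet_consistency,
    welch_t,
)
from .phenology import (
    arrival_vs_cone_regression,
    brood_patch_midpoint,
    brood_patch_vs_cone_regression,
    female_adult_subset,
)
from .registration import estimate_season_shifts, shift_vs_cone_regression
from .ringing import aggregate_sessions, filter_for_curve, first_arrival
from .regression import RegressionResult

__all__ = ["run_all", "ReportBundle", "RunManifest", "file_digest"]


@dataclass
class RunManifest:
    """Reproducibility record emitted with every report."""

    seed: int | None
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "version": self.version,
            "input_digests": dict(self.input_digests),
            "timings_s": {k: round(v, 4) for k, v in self.timings_s.items()},
        }


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ReportBundle:
    """Everything :func:`run_all` computes."""

    season_table: pd.DataFrame
    regressions: dict[str, RegressionResult]
    statistics: dict
    shifts: dict[str, pd.DataFrame]
    manifest: RunManifest

    def to_json_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, RegressionResult):
                return clean(obj.to_dict())
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, float)):
                v = float(obj)
                return v if np.isfinite(v) else None
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            if isinstance(obj, (pd.Timestamp,)):
                return str(obj.date())
            if obj is None or isinstance(obj, (str, bool)):
                return obj
            return str(obj)

        table = self.season_table.copy()
        for c in table.columns:
            if pd.api.types.is_datetime64_any_dtype(table[c]):
                table[c] = table[c].dt.strftime("%Y-%m-%d")
        return {
            "manifest": self.manifest.to_dict(),
            "season_table": clean(table.where(table.notna(), None).to_dict("records")),
            "regressions": clean(self.regressions),
            "statistics": clean(self.statistics),
        }

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.season_table.to_csv(out / "season_table.csv", index=False)
        for metric, df in self.shifts.items():
            df.to_csv(out / f"shifts_{metric}.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)


def run_all(
    captures: pd.DataFrame,
    rainfall: pd.Series,
    cone_scores: pd.DataFrame,
    isotopes: pd.DataFrame | None = None,
    cone_samples: pd.DataFrame | None = None,
    species: str = "SISKIN",
    seed: int | None = None,
    n_knots: int = 6,
    shift_bound: float = 40.0,
    grid_step: float = 0.5,
    input_digests: dict[str, str] | None = None,
) -> ReportBundle:
    """Run the complete analysis pipeline on one study's tables.

    ``cone_scores`` must carry ``cone_year``/``cone_score`` (the frame
    returned by :func:`mastphen.io.read_cone_scores`).  ``isotopes`` and
    ``cone_samples`` are optional; the corresponding blocks are omitted when
    absent.  Deterministic: identical inputs give identical output.
    """
    manifest = RunManifest(
        seed=seed, version=__version__, input_digests=input_digests or {}
    )
    t0 = time.perf_counter()

    sessions = aggregate_sessions(captures, species)
    sessions = sessions.merge(cone_scores, on="cone_year", how="left")
    manifest.timings_s["aggregate"] = time.perf_counter() - t0

    regressions: dict[str, RegressionResult] = {}
    statistics: dict = {}

    # --- season-level table -------------------------------------------------
    t0 = time.perf_counter()
    rain_table = within_year_rain_correlation(sessions, rainfall)
    all_dates = pd.to_datetime(captures["session_date"])
    all_cy = all_dates.dt.year.where(all_dates.dt.month >= 10, all_dates.dt.year - 1)
    netting = (
        pd.DataFrame({"cone_year": all_cy, "d": all_dates})
        .groupby("cone_year")["d"]
        .nunique()
        .rename("netting_days")
    )
    siskins = (
        captures.loc[captures["species"] == species]
        .assign(cone_year=all_cy[captures["species"] == species])
        .groupby("cone_year")
        .size()
        .rename("siskins_caught")
    )

    season_rows = []
    for year, grp in sessions.groupby("cone_year"):
        arr = first_arrival(grp)
        period = abundance_period(grp)
        mean_adults = np.nan
        if period is not None:
            inside = grp.loc[
                (grp["session_date"] >= period.start)
                & (grp["session_date"] <= period.end)
            ]
            mean_adults = float(inside["n_adults"].mean())
        aged_adults = grp["n_adult_aged"].sum()
        season_rows.append(
            {
                "cone_year": int(year),
                "cone_score": grp["cone_score"].iloc[0],
                "arrival_date": arr.date if arr.defined else pd.NaT,
                "arrival_offset": arr.oct31_offset if arr.defined else np.nan,
                "abundance_start": period.start if period else pd.NaT,
                "abundance_end": period.end if period else pd.NaT,
                "mean_adults": mean_adults,
                "first_year_proportion": (
                    grp["n_adult_first_year"].sum() / aged_adults
                    if aged_adults
                    else np.nan
                ),
            }
        )
    seasons = pd.DataFrame(season_rows)
    seasons = seasons.merge(
        rain_table.rename(columns={"r": "rain_correlation", "p": "rain_p"}),
        on="cone_year",
        how="left",
    )
    seasons = seasons.merge(netting, on="cone_year", how="left")
    seasons = seasons.merge(siskins, on="cone_year", how="left")

    # brood-patch midpoints
    females = female_adult_subset(captures, species)
    fem_dates = pd.to_datetime(females["session_date"])
    females = females.assign(
        cone_year=fem_dates.dt.year.where(fem_dates.dt.month >= 10, fem_dates.dt.year - 1),
        day_of_year=fem_dates.dt.dayofyear,
    )
    midpoints = {}
    for year, grp in females.groupby("cone_year"):
        est = brood_patch_midpoint(grp)
        midpoints[int(year)] = est.day if est.defined else np.nan
    seasons["brood_patch_midpoint"] = seasons["cone_year"].map(midpoints)

    jj = junejuly_fledgling_proportion(captures, species)
    seasons = seasons.merge(
        jj[["cone_year", "proportion"]].rename(
            columns={"proportion": "junejuly_fledgling_proportion"}
        ),
        on="cone_year",
        how="left",
    )
    manifest.timings_s["season_table"] = time.perf_counter() - t0

    # --- cross-season regressions ------------------------------------------
    t0 = time.perf_counter()
    regressions["arrival_vs_cone"] = arrival_vs_cone_regression(seasons)
    regressions["brood_patch_vs_cone"] = brood_patch_vs_cone_regression(seasons)
    regressions["junejuly_vs_cone"] = junejuly_vs_cone_regression(jj, cone_scores)
    regressions["adult_abundance"] = adult_abundance_model(seasons)
    regressions["carryover"] = carryover_age_ratio(seasons)
    for measure, name in (("mass_g", "juvenile_mass"), ("wing_mm", "juvenile_wing")):
        try:
            regressions[name] = juvenile_condition_model(
                captures, species, cone_scores, measure=measure
            )
        except ValueError:
            pass
    manifest.timings_s["season_regressions"] = time.perf_counter() - t0

    # --- curve registration -------------------------------------------------
    t0 = time.perf_counter()
    shifts: dict[str, pd.DataFrame] = {}
    for metric, name in (
        ("sex_ratio", "sex_ratio_shift"),
        ("fledgling_ratio", "fledgling_shift"),
    ):
        filtered = filter_for_curve(sessions, metric)
        statistics[f"n_curve_points_{metric}"] = int(len(filtered))
        _, sh = estimate_season_shifts(
            filtered, metric, n_knots=n_knots, bound=shift_bound, grid_step=grid_step
        )
        shifts[metric] = sh
        regressions[name] = shift_vs_cone_regression(sh, cone_scores)
    manifest.timings_s["registration"] = time.perf_counter() - t0

    # --- rainfall sign test -------------------------------------------------
    defined_r = rain_table.loc[rain_table["defined"], "r"]
    statistics["n_seasons_positive_rain_correlation"] = int((defined_r > 0).sum())
    statistics["n_seasons_with_rain_correlation"] = int(len(defined_r))
    statistics["rain_sign_test_p"] = (
        cross_year_sign_test(defined_r) if len(defined_r) else np.nan
    )

    # --- isotopes -----------------------------------------------------------
    if isotopes is not None and len(isotopes):
        t0 = time.perf_counter()
        iso = isotopes.merge(
            cone_scores, left_on="cone_year", right_on="cone_year", how="left"
        )
        feathers = iso.loc[iso["tissue"] == "feather"]
        sisk = feathers.loc[feathers["species"] == species]
        other = feathers.loc[feathers["species"] != species]
        if len(sisk) >= 2 and len(other) >= 2:
            t, df_w, p = welch_t(other["d15N"], sisk["d15N"])
            statistics["welch_d15N"] = {"t": t, "df": df_w, "p": p}
            t, df_w, p = welch_t(other["d13C"], sisk["d13C"])
            statistics["welch_d13C"] = {"t": t, "df": df_w, "p": p}
        statistics["siskin_feather_d15N_mean"] = float(sisk["d15N"].mean())
        statistics["siskin_feather_d15N_sd"] = float(sisk["d15N"].std())
        statistics["n_siskin_feathers"] = int(len(sisk))
        for iso_col in ("d15N", "d13C"):
            try:
                regressions[f"siskin_{iso_col}_vs_cone"] = isotope_vs_cone_regression(
                    iso, species, iso_col
                )
            except ValueError:
                pass
        seeds = iso.loc[iso["tissue"] == "seed"]
        expectation = DietExpectation(
            diet_d15N=float(seeds["d15N"].mean()) if len(seeds) else 0.09
        )
        statistics["expected_seed_diet_feather_d15N"] = expectation.feather_d15N
        high = sisk.loc[sisk["cone_score"] >= HIGH_CROP_SCORE]
        if len(high):
            verdict = seed_diet_consistency(
                float(high["d15N"].mean()), float(high["d13C"].mean()), expectation
            )
            statistics["high_crop_seed_diet"] = {
                "mean_d15N": float(high["d15N"].mean()),
                "mean_d13C": float(high["d13C"].mean()),
                "consistent": verdict.consistent,
                "d15N_margin": verdict.d15N_margin,
                "d13C_margin": verdict.d13C_margin,
            }
        manifest.timings_s["isotopes"] = time.perf_counter() - t0

    # --- cone retention -----------------------------------------------------
    if cone_samples is not None and len(cone_samples):
        from .environment import retention_curve

        retention = {}
        for site in cone_samples["site"].unique():
            curve = retention_curve(cone_samples, site)
            retention[str(site)] = {
                "final_mean_retention": float(curve["mean_retention"].iloc[-1]),
                "monotone_decreasing": curve.attrs.get("monotone_decreasing"),
                "n_months": int(len(curve)),
            }
        statistics["seed_retention"] = retention

    return ReportBundle(
        season_table=seasons,
        regressions=regressions,
        statistics=statistics,
        shifts=shifts,
        manifest=manifest,
    )
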
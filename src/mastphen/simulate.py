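"""Synthetic study generator.

Produces complete, internally consistent study bundles — capture records,
daily rainfall, autumn cone scores, feather/seed isotope samples and cone
dissection samples — with the statistical structure the analysis pipeline
assumes, so every stage can be exercised and parameter recovery measured
against known truth without any field data.

What is emulated, per season (cone year):

* a masting-like cone-score process alternating high and low crops;
* roughly weekly catch sessions from early November to early August;
* adult arrival ``a = alpha0 + alpha1 * c`` (days after 31 Oct) plus noise,
  followed by a ramp to a seasonal abundance plateau and a late-summer fade,
  with overdispersed (negative binomial) counts and a log-linear inflation
  by rainfall in the previous three days;
* a mid-season dip in the female share of sexed adults and a late-season
  rise in the fledgling share of aged birds, both rigid horizontal
  translates of fixed templates by their cone-score slopes;
* brood-patch scores on adult females following a rising logistic (midpoint
  shifted by cone score) that collapses again after breeding (re-feathering);
* fledgling feather isotopes mixed between a spruce-seed source and an
  invertebrate source with a +4 per-mil diet-to-feather nitrogen step, the
  seed fraction rising with cone score; non-siskin feathers mostly
  invertebrate-fed; seed reference samples;
* cone dissection samples from two sites with different seed-shed rates.

Determinism: all randomness flows from named substreams of one master seed
(:data:`STREAMS`), so regenerating one table never perturbs the others and
identical ``(config, seed)`` give identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "StudyData", "simulate_study", "simulate_null"]

#: Fixed substream indices of the master seed, one per generated component.
STREAMS: Mapping[str, int] = {
    "cone": 0,
    "rain": 1,
    "sessions": 2,
    "captures": 3,
    "isotopes": 4,
    "cone_samples": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), STREAMS[stream]]))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the generator, defaulting to the study conditions.

    Slopes are in days per cone-score point on the day scale (negative =
    earlier in big crop years) and templates are shifted around
    ``score_center`` so that changing a slope does not move the average
    season.  Defaults: arrival −5.8 d/point from 90 d after 31 Oct; sex-dip
    −7.5 d/point around calendar day 115; fledgling rise −7.3 d/point around
    day 160; brood-patch midpoint −3.5 d/point around day 105; feather δ15N
    residual s.d. 0.78 per mil around a seed (0.09 per mil) vs invertebrate
    mixture with a +4 per-mil trophic step.
    """

    n_seasons: int = 16
    start_year: int = 2005
    score_center: float = 5.0

    # catch-session cadence (season-day offsets are days after 31 Oct)
    session_start_offset: int = 1
    session_end_offset: int = 283
    mean_gap_days: int = 8
    gap_jitter_days: int = 3

    # masting cone-score process
    switch_prob: float = 0.6
    high_scores: tuple[int, ...] = (6, 7, 8, 9)
    low_scores: tuple[int, ...] = (1, 2, 3, 4)

    # arrival (days after 31 Oct)
    alpha0: float = 90.0
    alpha1: float = -5.8
    arrival_sd: float = 10.0

    # adult abundance
    amp0: float = 30.0
    amp_year: float = 1.0
    amp_cone: float = -2.0
    ramp_days: float = 40.0
    ramp_head_start: float = 4.0
    fade_offset: float = 270.0
    fade_width: float = 10.0
    nb_dispersion: float = 3.0

    # female-share dip (calendar day of year)
    dip_base: float = 0.5
    dip_depth: float = 0.25
    dip_width: float = 22.0
    dip_center_doy: float = 115.0
    b_sex: float = -7.5
    sex_unknown_prob: float = 0.02

    # fledgling-share rise
    rise_center_doy: float = 160.0
    rise_width: float = 12.0
    b_fled: float = -7.3
    plateau0: float = 0.40
    plateau_slope: float = 0.02

    # brood patch
    bp_mid_doy: float = 105.0
    bp_slope: float = -3.5
    bp_rate: float = 0.25
    bp_refeather_doy: float = 215.0
    bp_refeather_rate: float = 0.15

    # age structure
    age4_prob: float = 0.05
    firstyear_base_logit: float = 0.0
    carryover_effect: float = 0.0

    # rainfall and its effect on catches
    p_wet_given_wet: float = 0.7
    p_wet_given_dry: float = 0.35
    rain_gamma_shape: float = 0.8
    rain_gamma_scale: float = 8.0
    rain_effect: float = 0.012

    # isotopes
    seed_d15N: float = 0.09
    seed_d13C: float = -25.9
    fractionation_d15N: float = 4.0
    invert_diet_d15N: float = 2.6
    seed_feather_d13C: tuple[float, float] = (-24.4, -19.5)
    invert_feather_d13C: float = -24.2
    d15N_sd: float = 0.78
    d13C_sd: float = 0.6
    kappa0: float = -0.5
    kappa1: float = 0.35
    seed_fraction_sd: float = 0.05
    feathers_per_season: int = 10
    other_species_feathers: int = 6
    other_d15N_mean: float = 6.6
    other_d15N_cone_slope: float = 0.06
    n_seed_samples: int = 6

    # juvenile biometrics (monthly means, May/June/July)
    mass_month_means: tuple[float, float, float] = (12.2, 12.6, 13.0)
    mass_cone_slope: float = 0.0
    mass_sd: float = 0.7
    wing_month_means: tuple[float, float, float] = (69.0, 70.0, 71.0)
    wing_cone_slope: float = 0.0
    wing_sd: float = 1.5
    adult_mass_mean: float = 13.2
    adult_mass_sd: float = 0.9
    adult_wing_mean: float = 73.0
    adult_wing_sd: float = 1.8

    # other-species captures per session
    chaffinch_rate: float = 4.0

    # cone ripening study
    # per-month exponential shed rates; the slower site keeps ~10% of its
    # seeds into late July (month 9), the drier site sheds faster
    retention_sites: tuple[str, ...] = ("Argyll", "Perthshire")
    retention_decay: tuple[float, ...] = (0.256, 0.36)
    retention_trees: tuple[int, int] = (10, 30)
    scales_mean: float = 150.0
    scales_sd: float = 20.0

    # ---- deterministic templates (used by the generator and by tests) ----

    def arrival_offset(self, c: float) -> float:
        return self.alpha0 + self.alpha1 * (c - 0.0)

    def p_female(self, doy, c: float):
        m = self.dip_center_doy + self.b_sex * (c - self.score_center)
        doy = np.asarray(doy, dtype=float)
        return self.dip_base - self.dip_depth * np.exp(
            -((doy - m) ** 2) / (2.0 * self.dip_width**2)
        )

    def p_fledgling(self, doy, c: float):
        m = self.rise_center_doy + self.b_fled * (c - self.score_center)
        plateau = float(np.clip(self.plateau0 + self.plateau_slope * c, 0.05, 0.9))
        return plateau * _invlogit((np.asarray(doy, dtype=float) - m) / self.rise_width)

    def p_brood_patch(self, doy, c: float):
        m = self.bp_mid_doy + self.bp_slope * (c - self.score_center)
        doy = np.asarray(doy, dtype=float)
        rise = _invlogit(self.bp_rate * (doy - m))
        fall = _invlogit(-self.bp_refeather_rate * (doy - self.bp_refeather_doy))
        return rise * fall

    def seed_fraction(self, c: float) -> float:
        return float(_invlogit(self.kappa0 + self.kappa1 * c))


@dataclass
class StudyData:
    """One simulated study: the five input tables plus generator truth."""

    captures: pd.DataFrame
    rainfall: pd.DataFrame
    cone_scores: pd.DataFrame
    isotopes: pd.DataFrame
    cone_samples: pd.DataFrame
    truth: dict

    def write_csvs(self, out_dir) -> dict:
        """Write the five tables as CSV; returns {name: path}."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("captures", "rainfall", "cone_scores", "isotopes", "cone_samples"):
            df = getattr(self, name).copy()
            if "mass_g" in df.columns:
                df["mass_g"] = df["mass_g"].round(2)
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def _draw_cone_scores(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Masting-like alternation: persistent high/low states, score drawn
    within the state's band."""
    high = rng.random() < 0.5
    scores = np.empty(cfg.n_seasons, dtype=int)
    for i in range(cfg.n_seasons):
        if i > 0 and rng.random() < cfg.switch_prob:
            high = not high
        band = cfg.high_scores if high else cfg.low_scores
        scores[i] = rng.choice(band)
    return scores


def _draw_rainfall(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    start = pd.Timestamp(year=cfg.start_year, month=10, day=1)
    end = pd.Timestamp(year=cfg.start_year + cfg.n_seasons, month=9, day=30)
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    wet = np.empty(n, dtype=bool)
    u = rng.random(n)
    wet[0] = u[0] < 0.5
    for i in range(1, n):
        p = cfg.p_wet_given_wet if wet[i - 1] else cfg.p_wet_given_dry
        wet[i] = u[i] < p
    amounts = np.where(
        wet, rng.gamma(cfg.rain_gamma_shape, cfg.rain_gamma_scale, n), 0.0
    )
    return pd.DataFrame({"date": dates, "rain_mm": np.round(amounts, 1)})


def _session_offsets(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    offs, pos = [], float(cfg.session_start_offset)
    while pos <= cfg.session_end_offset:
        offs.append(int(round(pos)))
        pos += cfg.mean_gap_days + rng.integers(
            -cfg.gap_jitter_days, cfg.gap_jitter_days + 1
        )
    return np.array(offs, dtype=int)


def _neg_binomial(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 0.0)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        p = k / (k + mean[pos])
        out[pos] = rng.negative_binomial(k, p)
    return out


def simulate_study(config: SimulationConfig | None = None, seed: int = 0) -> StudyData:
    """Generate one complete study bundle, deterministic in (config, seed)."""
    cfg = config or SimulationConfig()
    scores = _draw_cone_scores(cfg, _rng(seed, "cone"))
    rainfall = _draw_rainfall(cfg, _rng(seed, "rain"))
    rain_by_date = rainfall.set_index("date")["rain_mm"]
    # 3-day antecedent totals for every calendar day, NaN-free by construction
    r3 = (
        rain_by_date.rolling(3).sum().shift(1).reindex(rain_by_date.index).fillna(0.0)
    )
    r3_mean = float(r3.mean())

    srng = _rng(seed, "sessions")
    crng = _rng(seed, "captures")
    cap_rows: list[pd.DataFrame] = []
    truth_seasons = []
    ring_counter = 0

    for i in range(cfg.n_seasons):
        year = cfg.start_year + i
        c = int(scores[i])
        oct31 = pd.Timestamp(year=year, month=10, day=31)
        offsets = _session_offsets(cfg, srng)
        dates = oct31 + pd.to_timedelta(offsets, unit="D")
        doy = dates.dayofyear.to_numpy(dtype=float)

        arrival = cfg.arrival_offset(c) + (
            crng.normal(0.0, cfg.arrival_sd) if cfg.arrival_sd > 0 else 0.0
        )
        if arrival >= cfg.session_end_offset:
            raise ValueError(
                f"season {year}: arrival {arrival:.1f} is after the last session"
            )

        amp = max(1.0, cfg.amp0 + cfg.amp_year * i + cfg.amp_cone * c)
        u = offsets.astype(float)
        ramp = np.clip((u - arrival + cfg.ramp_head_start) / cfg.ramp_days, 0.0, 1.0)
        ramp[u < arrival] = 0.0
        fade = _invlogit(-(u - cfg.fade_offset) / cfg.fade_width)
        rain3 = r3.loc[dates].to_numpy(dtype=float)
        rainmult = np.exp(cfg.rain_effect * (rain3 - r3_mean))
        lam_adult = amp * ramp * fade * rainmult

        n_adult = _neg_binomial(crng, lam_adult, cfg.nb_dispersion)
        pf = cfg.p_fledgling(doy, c)
        lam_fled = lam_adult * pf / np.maximum(1e-9, 1.0 - pf)
        n_fled = _neg_binomial(crng, lam_fled, cfg.nb_dispersion)

        n_sexed = crng.binomial(n_adult, 1.0 - cfg.sex_unknown_prob)
        n_female = crng.binomial(n_sexed, np.clip(cfg.p_female(doy, c), 0.0, 1.0))
        n_male = n_sexed - n_female
        n_unk = n_adult - n_sexed

        prev_c = float(scores[i - 1]) if i > 0 else cfg.score_center
        p_firstyear = float(
            _invlogit(
                cfg.firstyear_base_logit
                + cfg.carryover_effect * (prev_c - cfg.score_center)
            )
        )

        season_frames = []
        for j, d in enumerate(dates):
            rows = []
            n_tot_ad = int(n_adult[j])
            if n_tot_ad:
                sexes = np.concatenate(
                    [
                        np.repeat("F", n_female[j]),
                        np.repeat("M", n_male[j]),
                        np.repeat("U", n_unk[j]),
                    ]
                )
                is4 = crng.random(n_tot_ad) < cfg.age4_prob
                is5 = crng.random(n_tot_ad) < p_firstyear
                ages = np.where(is4, 4, np.where(is5, 5, 6))
                p_bp = float(np.clip(cfg.p_brood_patch(doy[j], c), 0.0, 1.0))
                formed = crng.random(n_tot_ad) < p_bp
                bp = np.where(
                    formed, crng.integers(3, 6, n_tot_ad), crng.integers(0, 3, n_tot_ad)
                ).astype(float)
                bp[sexes != "F"] = np.nan  # patch scored on females only
                rows.append(
                    pd.DataFrame(
                        {
                            "species": "SISKIN",
                            "euring_age": ages,
                            "fledgling": 0,
                            "sex": sexes,
                            "mass_g": crng.normal(
                                cfg.adult_mass_mean, cfg.adult_mass_sd, n_tot_ad
                            ),
                            "wing_mm": np.rint(
                                crng.normal(
                                    cfg.adult_wing_mean, cfg.adult_wing_sd, n_tot_ad
                                )
                            ).astype(int),
                            "brood_patch": bp,
                        }
                    )
                )
            n_f = int(n_fled[j])
            if n_f:
                month = d.month
                m_idx = {5: 0, 6: 1, 7: 2}.get(month, 2 if month > 7 else 0)
                mass = (
                    cfg.mass_month_means[m_idx]
                    + cfg.mass_cone_slope * c
                    + crng.normal(0.0, cfg.mass_sd, n_f)
                )
                wing = np.rint(
                    cfg.wing_month_means[m_idx]
                    + cfg.wing_cone_slope * c
                    + crng.normal(0.0, cfg.wing_sd, n_f)
                ).astype(int)
                rows.append(
                    pd.DataFrame(
                        {
                            "species": "SISKIN",
                            "euring_age": 3,
                            "fledgling": 1,
                            "sex": "U",
                            "mass_g": mass,
                            "wing_mm": wing,
                            "brood_patch": np.nan,
                        }
                    )
                )
            n_ch = int(crng.poisson(cfg.chaffinch_rate))
            if n_ch:
                rows.append(
                    pd.DataFrame(
                        {
                            "species": "CHAFFINCH",
                            "euring_age": crng.choice([3, 4, 5, 6], n_ch),
                            "fledgling": 0,
                            "sex": crng.choice(["F", "M"], n_ch),
                            "mass_g": crng.normal(21.5, 1.2, n_ch),
                            "wing_mm": np.rint(crng.normal(87, 2.0, n_ch)).astype(int),
                            "brood_patch": np.nan,
                        }
                    )
                )
            if rows:
                sess = pd.concat(rows, ignore_index=True)
                sess.insert(0, "session_date", d.date())
                season_frames.append(sess)
        if season_frames:
            season_df = pd.concat(season_frames, ignore_index=True)
            season_df["ring_id"] = [
                f"R{k:06d}" for k in range(ring_counter, ring_counter + len(season_df))
            ]
            ring_counter += len(season_df)
            cap_rows.append(season_df)

        truth_seasons.append(
            {
                "cone_year": year,
                "cone_score": c,
                "arrival_offset": float(arrival),
                "dip_center_doy": cfg.dip_center_doy
                + cfg.b_sex * (c - cfg.score_center),
                "rise_center_doy": cfg.rise_center_doy
                + cfg.b_fled * (c - cfg.score_center),
                "bp_mid_doy": cfg.bp_mid_doy + cfg.bp_slope * (c - cfg.score_center),
                "seed_fraction": cfg.seed_fraction(c),
            }
        )

    captures = pd.concat(cap_rows, ignore_index=True)
    captures["mass_g"] = captures["mass_g"].round(2)
    captures["time_min"] = _rng(seed, "sessions").choice(
        np.arange(420, 961, 30), size=len(captures)
    )
    captures = captures[
        [
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
        ]
    ]

    cone_scores = pd.DataFrame(
        {"autumn_year": cfg.start_year + np.arange(cfg.n_seasons), "score": scores}
    )

    isotopes = _draw_isotopes(cfg, scores, _rng(seed, "isotopes"))
    cone_samples = _draw_cone_samples(cfg, _rng(seed, "cone_samples"))

    truth = {
        "config": cfg,
        "seasons": pd.DataFrame(truth_seasons),
        "slopes": {
            "arrival": cfg.alpha1,
            "sex_dip": cfg.b_sex,
            "fledgling_rise": cfg.b_fled,
            "brood_patch": cfg.bp_slope,
        },
    }
    return StudyData(captures, rainfall, cone_scores, isotopes, cone_samples, truth)


def _draw_isotopes(
    cfg: SimulationConfig, scores: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    seed_mid = float(np.mean(cfg.seed_feather_d13C))
    rows = []
    sid = 0
    for i, c in enumerate(scores):
        year = cfg.start_year + i
        f = np.clip(
            cfg.seed_fraction(c)
            + rng.normal(0.0, cfg.seed_fraction_sd, cfg.feathers_per_season),
            0.0,
            1.0,
        )
        diet_n = f * cfg.seed_d15N + (1.0 - f) * cfg.invert_diet_d15N
        d15n = diet_n + cfg.fractionation_d15N + rng.normal(
            0.0, cfg.d15N_sd, cfg.feathers_per_season
        )
        d13c = (
            f * seed_mid
            + (1.0 - f) * cfg.invert_feather_d13C
            + rng.normal(0.0, cfg.d13C_sd, cfg.feathers_per_season)
        )
        for k in range(cfg.feathers_per_season):
            rows.append(
                ("F{:04d}".format(sid), "SISKIN", year, "feather", d15n[k], d13c[k])
            )
            sid += 1
        n_oth = cfg.other_species_feathers
        oth_n = rng.normal(
            cfg.other_d15N_mean + cfg.other_d15N_cone_slope * (c - cfg.score_center),
            0.7,
            n_oth,
        )
        oth_c = rng.normal(cfg.invert_feather_d13C, 0.7, n_oth)
        for k in range(n_oth):
            rows.append(
                ("F{:04d}".format(sid), "CHAFFINCH", year, "feather", oth_n[k], oth_c[k])
            )
            sid += 1
    for k in range(cfg.n_seed_samples):
        rows.append(
            (
                "S{:04d}".format(k),
                "SITKA_SPRUCE",
                cfg.start_year,
                "seed",
                rng.normal(cfg.seed_d15N, 0.1),
                rng.normal(cfg.seed_d13C, 0.3),
            )
        )
    df = pd.DataFrame(
        rows, columns=["sample_id", "species", "cone_year", "tissue", "d15N", "d13C"]
    )
    return df.round({"d15N": 2, "d13C": 2})


def _draw_cone_samples(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly cone dissections over one ripening year (Oct–Jul), two sites."""
    start = pd.Timestamp(year=cfg.start_year + 1, month=10, day=15)
    rows = []
    for site, decay in zip(cfg.retention_sites, cfg.retention_decay):
        for m in range(10):
            when = start + pd.DateOffset(months=m)
            retention = float(np.exp(-decay * m))
            n_trees = int(rng.integers(cfg.retention_trees[0], cfg.retention_trees[1] + 1))
            scales = np.maximum(
                40, np.rint(rng.normal(cfg.scales_mean, cfg.scales_sd, n_trees))
            ).astype(int)
            seeds = rng.binomial(2 * scales, retention)
            for sc, sd in zip(scales, seeds):
                rows.append((site, when.date(), int(sc), int(sd)))
    return pd.DataFrame(
        rows, columns=["site", "collection_date", "n_scales", "n_seeds_extracted"]
    )


def simulate_null(config: SimulationConfig | None = None, seed: int = 0) -> StudyData:
    """Same design with every cone-score effect zeroed (type-I calibration)."""
    cfg = config or SimulationConfig()
    return simulate_study(null_config(cfg), seed)


def null_config(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with all cone-score couplings set to zero."""
    return replace(
        cfg,
        alpha1=0.0,
        b_sex=0.0,
        b_fled=0.0,
        bp_slope=0.0,
        kappa1=0.0,
        amp_cone=0.0,
        plateau_slope=0.0,
        carryover_effect=0.0,
        mass_cone_slope=0.0,
        wing_cone_slope=0.0,
        other_d15N_cone_slope=0.0,
    )
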
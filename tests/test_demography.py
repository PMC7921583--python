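"""Fledgling output, adult abundance, juvenile condition and carry-over."""

import numpy as np
import pandas as pd
import pytest

from mastphen import (
    adult_abundance_model,
    carryover_age_ratio,
    junejuly_fledgling_proportion,
    junejuly_vs_cone_regression,
    juvenile_condition_model,
    national_juvenile_regression,
)
from conftest import records


class TestJuneJulyProportion:
    def test_proportion_of_aged_birds(self):
        rows = [("2012-06-15", "SISKIN", f"A{i}", 3, 1, "U") for i in range(30)]
        rows += [("2012-07-01", "SISKIN", f"B{i}", 4, 0, "M") for i in range(30)]
        rows += [("2012-05-20", "SISKIN", "C0", 3, 1, "U")]  # outside June-July
        out = junejuly_fledgling_proportion(records(rows), "SISKIN")
        assert len(out) == 1
        assert out.iloc[0]["proportion"] == 0.5

    def test_zero_fledglings(self):
        rows = [("2012-06-15", "SISKIN", f"A{i}", 4, 0, "M") for i in range(5)]
        out = junejuly_fledgling_proportion(records(rows), "SISKIN")
        assert out.iloc[0]["proportion"] == 0.0

    def test_duplication_invariance(self):
        """Doubling the whole record set leaves every proportion unchanged."""
        rows = [("2012-06-15", "SISKIN", f"A{i}", 3, 1, "U") for i in range(10)]
        rows += [("2012-07-01", "SISKIN", f"B{i}", 5, 0, "F") for i in range(20)]
        df = records(rows)
        once = junejuly_fledgling_proportion(df, "SISKIN")
        twice = junejuly_fledgling_proportion(
            pd.concat([df, df], ignore_index=True), "SISKIN"
        )
        assert twice.iloc[0]["proportion"] == once.iloc[0]["proportion"]

    def test_positive_slope_on_synthetic_study(self, default_study, default_bundle):
        """Fledgling output grows with cone score in the generator, and the
        regression recovers a positive slope."""
        res = default_bundle.regressions["junejuly_vs_cone"]
        assert res.slope > 0
        assert res.p < 0.05


class TestAdultAbundanceModel:
    def _seasons(self, response):
        n = len(response)
        return pd.DataFrame(
            {
                "cone_year": 2005 + np.arange(n),
                "cone_score": [1, 5, 3, 8, 2, 9, 4, 7, 6, 2][:n],
                "mean_adults": response,
            }
        )

    def test_noiseless_coefficients_recovered_exactly(self):
        s = self._seasons([0.0] * 10)
        s["mean_adults"] = 2.0 * s["cone_year"] - 3.0 * s["cone_score"]
        res = adult_abundance_model(s)
        assert res.params["cone_year"] == pytest.approx(2.0)
        assert res.params["cone_score"] == pytest.approx(-3.0)
        assert res.slope == pytest.approx(-3.0)

    def test_single_season_rejected(self):
        with pytest.raises(ValueError):
            adult_abundance_model(self._seasons([30.0]))

    def test_cone_term_null_calibrated(self):
        """Response independent of cone score: per-term F rejects ~5%."""
        rng = np.random.default_rng(13)
        rej, reps = 0, 500
        for _ in range(reps):
            s = self._seasons(rng.normal(30, 5, 10) + 0.5 * np.arange(10))
            if adult_abundance_model(s).p < 0.05:
                rej += 1
        assert 0.02 <= rej / reps <= 0.08


class TestJuvenileConditionModel:
    def _records(self, n_june=20, n_july=20, may_extra=0.0, cone_effect=0.0):
        rows = []
        rng = np.random.default_rng(0)
        for year, score in [(2011, 2), (2012, 8), (2013, 5)]:
            for month, n in ((5, 12), (6, n_june), (7, n_july)):
                for i in range(n):
                    rows.append(
                        {
                            "session_date": pd.Timestamp(year + 1, month, 10),
                            "species": "SISKIN",
                            "ring_id": f"{year}{month}{i}",
                            "euring_age": 3,
                            "fledgling": 1,
                            "sex": "U",
                            "mass_g": 12.0 + 0.3 * month + cone_effect * score
                            + rng.normal(0, 0.01),
                            "wing_mm": 70,
                            "brood_patch": np.nan,
                        }
                    )
        return pd.DataFrame(rows)

    def _scores(self):
        return pd.DataFrame(
            {"cone_year": [2011, 2012, 2013], "cone_score": [2, 8, 5]}
        )

    def test_month_effect_without_cone_effect(self):
        res = juvenile_condition_model(self._records(), "SISKIN", self._scores())
        assert abs(res.slope) < 0.01
        assert res.p > 0.05

    def test_cone_effect_detected_when_present(self):
        res = juvenile_condition_model(
            self._records(cone_effect=0.2), "SISKIN", self._scores()
        )
        assert res.slope == pytest.approx(0.2, abs=0.01)
        assert res.p < 0.01

    def test_small_cells_excluded_at_boundary(self):
        """A 9-capture cell is dropped, a 10-capture cell kept."""
        df9 = self._records(n_june=9)
        res9 = juvenile_condition_model(df9, "SISKIN", self._scores())
        df10 = self._records(n_june=10)
        res10 = juvenile_condition_model(df10, "SISKIN", self._scores())
        assert res10.n - res9.n == 3  # one June cell per season re-enters

    def test_identical_means_give_zero_slopes(self):
        df = self._records()
        df["mass_g"] = 12.5
        res = juvenile_condition_model(df, "SISKIN", self._scores())
        assert res.slope == pytest.approx(0.0, abs=1e-9)


class TestCarryover:
    def _seasons(self, props, scores):
        n = len(props)
        return pd.DataFrame(
            {
                "cone_year": 2005 + np.arange(n),
                "cone_score": scores[:n],
                "first_year_proportion": props,
            }
        )

    def test_constant_proportion_gives_zero_slope(self):
        s = self._seasons([0.5] * 8, [1, 5, 3, 8, 2, 9, 4, 7])
        res = carryover_age_ratio(s)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_injected_effect_recovered(self):
        scores = np.array([1, 5, 3, 8, 2, 9, 4, 7, 6, 2])
        props = np.empty(10)
        props[0] = 0.5
        props[1:] = 0.3 + 0.03 * scores[:-1]  # driven by previous score
        res = carryover_age_ratio(self._seasons(props, scores))
        assert res.slope == pytest.approx(0.03, abs=1e-9)
        assert res.term == "prev_cone_score"

    def test_no_effect_rejects_at_nominal_rate(self, default_study, default_bundle):
        """The default generator has zero carry-over; a single study should
        usually fail to reject (checked properly in the calibration suite)."""
        res = default_bundle.regressions["carryover"]
        assert res.n == 15  # first season has no previous score


class TestNationalRegression:
    def _table(self, props, years=None):
        years = years if years is not None else 2006 + np.arange(len(props))
        total = np.full(len(props), 1000)
        return pd.DataFrame(
            {
                "year": years,
                "juveniles": np.round(total * np.asarray(props)).astype(int),
                "total": total,
            }
        )

    def _scores(self, scores, start=2005):
        return pd.DataFrame(
            {"cone_year": start + np.arange(len(scores)), "cone_score": scores}
        )

    def test_linear_proportions_recovered(self):
        scores = np.array([2, 8, 5, 3, 9, 1, 6, 7])
        props = 0.2 + 0.05 * scores
        res = national_juvenile_regression(self._table(props), self._scores(scores))
        assert res.slope == pytest.approx(0.05, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_closed_form_least_squares_oracle(self):
        """Slope agrees with the closed-form covariance/variance ratio."""
        rng = np.random.default_rng(17)
        scores = np.array([2, 8, 5, 3, 9, 1, 6, 7])
        props = np.clip(0.3 + 0.02 * scores + rng.normal(0, 0.03, 8), 0, 1)
        table = self._table(props)
        res = national_juvenile_regression(table, self._scores(scores))
        p = table["juveniles"] / table["total"]
        expected = np.cov(scores, p, ddof=1)[0, 1] / np.var(scores, ddof=1)
        assert res.slope == pytest.approx(expected, rel=1e-9)

    def test_unmatched_years_listed_in_error(self):
        with pytest.raises(ValueError, match="2008"):
            national_juvenile_regression(
                self._table([0.3, 0.4, 0.5]), self._scores([5, 6], start=2005)
            )
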
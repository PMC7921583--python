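"""Shared linear-model results.

Every cross-season test in the package is an ordinary least-squares fit with
an ANOVA-style F test, reported the same way: coefficients, F with its
degrees of freedom, p, R² and n.  :func:`simple_ols` covers the one-predictor
regressions (arrival, brood-patch midpoint, curve shifts, isotopes …);
:func:`additive_ols` the additive models (cone score + year, cone score +
month) where a per-term F is wanted.  Raw p-values are reported throughout;
no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = ["RegressionResult", "simple_ols", "additive_ols"]


@dataclass(frozen=True)
class RegressionResult:
    """OLS summary in the form the cross-season analyses report.

    ``slope`` is the coefficient of the named focal predictor (the only
    predictor, for simple regressions).  ``f_stat``/``p`` refer to the focal
    term's F test, which for a simple regression is the overall ANOVA F with
    (1, n−2) degrees of freedom and satisfies F = (n−2)·R²/(1−R²).
    """

    slope: float
    intercept: float
    f_stat: float
    df_num: int
    df_den: int
    p: float
    r_squared: float
    n: int
    term: str = "x"
    params: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "slope": self.slope,
            "intercept": self.intercept,
            "F": self.f_stat,
            "df": [self.df_num, self.df_den],
            "p": self.p,
            "r_squared": self.r_squared,
            "n": self.n,
            "params": dict(self.params),
        }


def simple_ols(x, y, term: str = "x") -> RegressionResult:
    """OLS of ``y`` on a single predictor ``x`` with the overall F test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 points for a regression, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope is not identifiable")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if np.ptp(y) == 0:  # constant response: slope 0, nothing explained
        f_stat, p, r2 = 0.0, 1.0, 0.0
    else:
        f_stat, p, r2 = float(fit.fvalue), float(fit.f_pvalue), float(fit.rsquared)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_stat=f_stat,
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        p=p,
        r_squared=r2,
        n=n,
        term=term,
        params={"intercept": float(fit.params[0]), term: float(fit.params[1])},
    )


def additive_ols(
    data: pd.DataFrame,
    response: str,
    focal: str,
    covariates: tuple[str, ...] = (),
    categorical: tuple[str, ...] = (),
) -> RegressionResult:
    """Additive OLS ``response ~ focal + covariates`` with a per-term F.

    The reported F/p are the type-II ANOVA test of the *focal* term (a
    continuous predictor), with the covariates held in the model; categorical
    covariates are wrapped in ``C()``.  Raises on collinear predictors.
    """
    terms = [focal] + [f"C({c})" if c in categorical else c for c in covariates]
    formula = f"{response} ~ " + " + ".join(terms)
    df = data.dropna(subset=[response, focal, *covariates])
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("collinear predictors in additive model")
    table = anova_lm(fit, typ=2)
    row = table.loc[focal]
    return RegressionResult(
        slope=float(fit.params[focal]),
        intercept=float(fit.params.get("Intercept", np.nan)),
        f_stat=float(row["F"]),
        df_num=int(row["df"]),
        df_den=int(table.loc["Residual", "df"]),
        p=float(row["PR(>F)"]),
        r_squared=float(fit.rsquared),
        n=int(fit.nobs),
        term=focal,
        params={k: float(v) for k, v in fit.params.items()},
    )
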
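"""Curve registration for seasonal composition ratios.

The phenological signal of interest is a *shape* — a mid-season dip in the
proportion of females among sexed adults (females disappear into incubation),
or a late-season rise in the proportion of fledglings — whose horizontal
position moves from year to year.  The estimator here:

1. fits one pooled natural cubic spline to the ratio-vs-day scatter of all
   seasons jointly (:func:`fit_pooled_curve`), then
2. slides that fixed curve horizontally for each season to minimize the sum
   of squared misfit to that season's points (:func:`estimate_year_shift`),
   recording the signed shift in days as the season's earliness/lateness.

A rigid horizontal shift is the only registration allowed: no amplitude or
nonlinear time warping.  Per-season shifts are then regressed on the autumn
cone-crop score (:func:`shift_vs_cone_regression`) on the *earliness* scale
(days earlier = minus the shift), matching the convention in which a
positive slope means the pattern happens earlier in big crop years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.optimize import minimize_scalar

from .regression import RegressionResult, simple_ols

__all__ = [
    "SplineCurve",
    "ShiftEstimate",
    "fit_pooled_curve",
    "estimate_year_shift",
    "estimate_season_shifts",
    "shift_vs_cone_regression",
]


@dataclass(frozen=True)
class SplineCurve:
    """Least-squares natural cubic spline, evaluable anywhere.

    Natural boundary conditions (zero second derivative at the boundary
    knots) make the curve linear beyond the outermost knots; evaluation
    outside ``support`` continues that tangent line explicitly, so the fit
    can be slid past the edge of the data without polynomial blow-up.
    """

    knots: np.ndarray
    coefs: np.ndarray
    design_info: object
    support: tuple[float, float]

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.support
        inner = np.clip(x, lo, hi)
        y = self._eval_basis(inner)
        # linear continuation beyond the support, slope from a small secant
        h = 1e-4 * (hi - lo)
        below, above = x < lo, x > hi
        if below.any():
            slope = (self._eval_basis([lo + h]) - self._eval_basis([lo])) / h
            y[below] += slope[0] * (x[below] - lo)
        if above.any():
            slope = (self._eval_basis([hi]) - self._eval_basis([hi - h])) / h
            y[above] += slope[0] * (x[above] - hi)
        return y

    def _eval_basis(self, x) -> np.ndarray:
        (mat,) = build_design_matrices([self.design_info], {"x": np.asarray(x)})
        return np.asarray(mat) @ self.coefs


def fit_pooled_curve(
    t, ratio, n_knots: int = 6, support: tuple[float, float] | None = None
) -> SplineCurve:
    """Fit the pooled natural cubic spline to a ratio-vs-day scatter.

    ``n_knots`` interior knots are placed at equally spaced quantiles of the
    observed days; boundary knots sit at the data range (or the explicit
    ``support``).  The fit is plain least squares in the natural cubic basis,
    so the spline space contains all constants and straight lines, and the
    residual sum of squares can only fall as ``n_knots`` grows.
    """
    t = np.asarray(t, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    ok = np.isfinite(t) & np.isfinite(ratio)
    t, ratio = t[ok], ratio[ok]
    if t.size < n_knots + 2:
        raise ValueError(f"need at least n_knots + 2 = {n_knots + 2} points")
    if np.ptp(t) == 0:
        raise ValueError("all days identical: spline design is singular")
    lo, hi = support if support is not None else (t.min(), t.max())
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.quantile(t, qs)
    interior = interior[(interior > lo) & (interior < hi)]
    mat = dmatrix(
        "cr(x, knots=interior, lower_bound=lo, upper_bound=hi)",
        {"x": t, "interior": interior, "lo": lo, "hi": hi},
    )
    coefs, *_ = np.linalg.lstsq(np.asarray(mat), ratio, rcond=None)
    return SplineCurve(
        knots=np.concatenate([[lo], interior, [hi]]),
        coefs=coefs,
        design_info=mat.design_info,
        support=(float(lo), float(hi)),
    )


@dataclass(frozen=True)
class ShiftEstimate:
    """Season-level horizontal shift of the pooled curve.

    ``shift_days`` is positive when the season's pattern ran *later* than
    the pooled curve; ``earliness_days = -shift_days``.  ``defined`` is
    False when the season had too few usable sessions.
    """

    cone_year: int | None
    shift_days: float
    misfit: float
    n: int
    defined: bool = True

    @property
    def earliness_days(self) -> float:
        return -self.shift_days


def _sse(curve: SplineCurve, t: np.ndarray, y: np.ndarray, s: float) -> float:
    return float(np.sum((y - curve(t - s)) ** 2))


def estimate_year_shift(
    curve: SplineCurve,
    t,
    ratio,
    bound: float = 40.0,
    grid_step: float = 0.5,
    cone_year: int | None = None,
) -> ShiftEstimate:
    """Shift minimizing the squared misfit of one season to the pooled curve.

    A full grid search on [−bound, bound] at ``grid_step`` guards against
    local minima; ties break toward the smaller |shift|.  The winning grid
    cell is then refined by bounded scalar minimization, so the returned
    shift is accurate to well below the grid step.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(ratio, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 3:
        return ShiftEstimate(cone_year, np.nan, np.nan, int(t.size), defined=False)
    if bound <= 0:
        raise ValueError("shift bound must be positive")

    grid = np.arange(-bound, bound + grid_step / 2, grid_step)
    # evaluate all shifts at once: row i = curve(t - grid[i])
    shifted = curve((t[None, :] - grid[:, None]).ravel()).reshape(grid.size, t.size)
    sse = np.sum((y[None, :] - shifted) ** 2, axis=1)
    order = np.lexsort((np.abs(grid), sse))  # ties -> smaller |s|
    best = grid[order[0]]

    lo = max(-bound, best - grid_step)
    hi = min(bound, best + grid_step)
    res = minimize_scalar(
        lambda s: _sse(curve, t, y, s), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4},
    )
    s_opt, f_opt = float(res.x), float(res.fun)
    if sse[order[0]] < f_opt:  # keep the grid point if refinement went uphill
        s_opt, f_opt = float(best), float(sse[order[0]])
    return ShiftEstimate(cone_year, s_opt, f_opt, int(t.size))


def estimate_season_shifts(
    sessions: pd.DataFrame,
    metric: str,
    n_knots: int = 6,
    bound: float = 40.0,
    grid_step: float = 0.5,
) -> tuple[SplineCurve, pd.DataFrame]:
    """Pooled fit plus per-season shifts for filtered session summaries.

    ``sessions`` must already have passed :func:`mastphen.ringing.filter_for_curve`
    for the same metric; the pooled curve is fit once on all seasons jointly
    and never re-fit inside the shift loop.
    """
    curve = fit_pooled_curve(sessions["day_of_year"], sessions[metric], n_knots)
    rows = []
    for year, grp in sessions.groupby("cone_year"):
        est = estimate_year_shift(
            curve, grp["day_of_year"], grp[metric],
            bound=bound, grid_step=grid_step, cone_year=int(year),
        )
        rows.append(
            {
                "cone_year": int(year),
                "shift_days": est.shift_days,
                "earliness_days": est.earliness_days,
                "misfit": est.misfit,
                "n": est.n,
                "defined": est.defined,
            }
        )
    return curve, pd.DataFrame(rows).sort_values("cone_year").reset_index(drop=True)


def shift_vs_cone_regression(shifts: pd.DataFrame, cone_scores: pd.DataFrame) -> RegressionResult:
    """OLS of season earliness (days earlier) on autumn cone-crop score.

    A positive slope means the seasonal pattern ran earlier in years with a
    bigger cone crop; the day-scale slope of the raw shift is its negative.
    """
    merged = shifts.loc[shifts["defined"]].merge(cone_scores, on="cone_year")
    return simple_ols(
        merged["cone_score"], merged["earliness_days"], term="cone_score"
    )
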
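"""Reduced major axis (Model II) regression with slope tests and shape labels.

Swimmer density is regressed on resident density (or biomass) on log10
scale.  Because the predictor — a mean over 12 cores — is itself measured
with error, an ordinary least-squares slope would be attenuated; the
reduced major axis (geometric mean) slope

    b = sign(r) * SD_y / SD_x

is the appropriate Model II estimate.  Two hypotheses are tested:

* ``slope = 0`` via the standard Student's t on the correlation,
  ``t = r sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` df — significance is
  equivalent to the correlation test;
* ``slope = 1`` (only meaningful once the slope differs from 0) via
  Clark's T on the log slope ratio,

      T = |log10(b / b0)| * sqrt((n-3) / (1-r^2)),

  referred to a t distribution with the non-integer degrees of freedom
  ``nu = (n-3) / (1 + r^4 / 2)`` (Clarke 1980; McArdle 1988).

On a log-log scale the fitted slope labels the shape of the
density-dependence relationship: a significant slope below 1 is ascending
but decelerating (a decreasing *proportion* swims as resident density
rises), a slope indistinguishable from 1 is proportional, and a slope
above 1 is ascending and accelerating.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RmaFit",
    "rma_fit",
    "test_slope_zero",
    "test_slope_one",
    "classify_shape",
    "RMARegression",
]

SHAPES = ("ascending-accelerating", "proportional", "ascending-decelerating",
          "none")


class GatingError(RuntimeError):
    """Clark's test requested although the slope does not differ from 0."""


class DegenerateFitError(ValueError):
    """Raised when the regression inputs admit no slope (zero x variance)."""


@dataclass(frozen=True)
class RmaFit:
    """RMA estimates, both slope tests and the relationship-shape label."""

    slope: float
    intercept: float
    slope_se: float
    r: float
    n: int
    df0: int
    t0: float
    p0: float
    df1: float | None = None
    t1: float | None = None
    p1: float | None = None
    shape: str = "none"
    alpha: float = 0.05

    def summary(self) -> str:
        lines = [
            f"RMA regression (n={self.n})",
            f"  slope = {self.slope:.4f} +/- {self.slope_se:.4f}, "
            f"intercept = {self.intercept:.4f}, r = {self.r:.4f}",
            f"  H0 slope=0: t({self.df0}) = {self.t0:.3f}, p = {self.p0:.4g}",
        ]
        if self.t1 is not None:
            lines.append(f"  H0 slope=1: T({self.df1:.1f}) = {self.t1:.3f}, "
                         f"p = {self.p1:.4g}")
        else:
            lines.append("  H0 slope=1: not tested (slope=0 not rejected)")
        lines.append(f"  shape: {self.shape}")
        return "\n".join(lines)


def _slope_zero(r: float, n: int) -> tuple[int, float, float]:
    df = n - 2
    if abs(r) >= 1.0:
        return df, float(np.sign(r) * np.inf), 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return df, float(t), float(2 * stats.t.sf(abs(t), df))


def _clark(slope: float, r: float, n: int, hypothesized: float = 1.0
           ) -> tuple[float, float, float]:
    """Clark's T, its non-integer df and two-sided p for H0: slope = b0.

    Operates on the slope magnitude (the log ratio is undefined for
    opposite-signed slopes; in intended use slopes are positive).
    """
    r2 = r * r
    log_ratio = abs(np.log10(abs(slope) / hypothesized))
    df = (n - 3) / (1.0 + r2 * r2 / 2.0)
    if r2 >= 1.0:    # exact fit: any non-unit ratio is infinitely significant
        at_null = log_ratio < 1e-12
        return df, (0.0 if at_null else float("inf")), (1.0 if at_null else 0.0)
    t = log_ratio * np.sqrt((n - 3) / (1.0 - r2))
    return df, float(t), float(2 * stats.t.sf(t, df))


def rma_fit(x, y, *, alpha: float = 0.05, hypothesized_slope: float = 1.0
            ) -> RmaFit:
    """Fit the reduced major axis of ``y`` on ``x`` (both already log10).

    Requires at least 3 complete finite pairs and non-zero variance in
    ``x``.  The slope-vs-1 test is run (and the shape labelled) only when
    the slope differs significantly from 0 at ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0:
        raise DegenerateFitError("x has zero variance; RMA slope undefined")

    if sy == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(x, y)[0, 1])
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * sy / sx)
    intercept = float(np.mean(y) - slope * np.mean(x))
    df0, t0, p0 = _slope_zero(r, n)
    se = float(abs(slope) * np.sqrt((1.0 - r * r) / df0)) if df0 > 0 else float("nan")

    df1 = t1 = p1 = None
    shape = "none"
    if p0 < alpha:
        df1, t1, p1 = _clark(slope, r, n, hypothesized_slope)
        if p1 < alpha:
            shape = ("ascending-decelerating" if slope < hypothesized_slope
                     else "ascending-accelerating")
        else:
            shape = "proportional"
    return RmaFit(slope=slope, intercept=intercept, slope_se=se, r=r, n=n,
                  df0=df0, t0=t0, p0=p0, df1=df1, t1=t1, p1=p1,
                  shape=shape, alpha=alpha)


def test_slope_zero(fit: RmaFit) -> tuple[float, float]:
    """Student's t and two-sided p for H0: slope = 0."""
    return fit.t0, fit.p0


def test_slope_one(fit: RmaFit) -> tuple[float, float, float]:
    """Clark's (T, df, p) for H0: slope = 1; gated on slope != 0."""
    if fit.p0 >= fit.alpha:
        raise GatingError(
            "Clark's test applies only after the slope differs from 0 "
            f"(p0 = {fit.p0:.3g} >= alpha = {fit.alpha})")
    if fit.t1 is None:
        df1, t1, p1 = _clark(fit.slope, fit.r, fit.n)
        return t1, df1, p1
    return fit.t1, fit.df1, fit.p1


def classify_shape(fit: RmaFit, alpha: float = 0.05) -> str:
    """Label the log-log relationship shape at significance ``alpha``."""
    if fit.p0 >= alpha:
        return "none"
    df1, t1, p1 = (fit.df1, fit.t1, fit.p1)
    if p1 is None:
        df1, t1, p1 = _clark(fit.slope, fit.r, fit.n)
    if p1 < alpha:
        return ("ascending-decelerating" if fit.slope < 1.0
                else "ascending-accelerating")
    return "proportional"


class RMARegression:
    """Model-style wrapper around :func:`rma_fit`.

    ``x`` and ``y`` are paired site x round cell values, already
    log10-transformed (resident density or biomass on x, swimmer density
    on y).
    """

    def __init__(self, y, x):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)

    def fit(self, *, alpha: float = 0.05) -> RmaFit:
        return rma_fit(self.x, self.y, alpha=alpha)
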
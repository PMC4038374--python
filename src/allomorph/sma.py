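"""Standardized (reduced) major axis line fitting and allometry tests.

Model II regression for log-log allometry: both variables carry biological
and measurement error, so the fitted line is the standardized major axis
(SMA, historically "reduced major axis"), whose slope is

    b = sign(r) * SD(y) / SD(x)

on log10-transformed data. Under geometric similarity a segment mass scales
as (body mass)^1.0 and as (limb length)^3.0, so isometry is a point null on
this slope, tested two ways that are reported side by side: an F test of the
null slope, and exclusion of the null from the slope's confidence interval.

Across groups (e.g. the five limb segments against a common body-size axis),
a likelihood-ratio test asks whether one shared slope fits all groups, and a
Wald test compares the lines' elevations (intercepts at the common slope).

Confidence-interval construction for the slope follows the standard SMA
result: with B = F(1-alpha; 1, n-2) * (1 - r^2) / (n - 2), the limits are
b * (sqrt(B + 1) -/+ sqrt(B)). The intercept interval uses
Var(a) = s^2_resid / n + xbar^2 * Var(b), with Var(b) implied by the slope
interval half-width — an approximation adequate to ~0.05 on these data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .dataset import VariablePair
from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "SMAFit",
    "SlopeHypothesisTest",
    "CommonSlopeResult",
    "ElevationTestResult",
    "fit_sma",
    "test_slope",
    "ci_excludes",
    "test_common_slope",
    "test_elevation",
    "pairwise_elevation",
]


@dataclass(frozen=True)
class SMAFit:
    """SMA estimates on the log10 scale, with confidence intervals."""

    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    alpha: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    label: str = ""


@dataclass(frozen=True)
class SlopeHypothesisTest:
    """F test of a hypothesized SMA slope b0."""

    b0: float
    F: float
    df: tuple[int, int]
    p: float
    reject: bool
    alpha: float


@dataclass(frozen=True)
class CommonSlopeResult:
    """Likelihood-ratio test for a single slope shared across groups."""

    b_common: float
    statistic: float
    df: int
    p: float
    group_fits: tuple[SMAFit, ...]
    alpha: float

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class ElevationTestResult:
    """Wald test comparing group elevations at a shared slope."""

    statistic: float
    df: int
    p: float
    b_common_used: float
    elevations: tuple[float, ...] = field(default=())
    alpha: float = 0.05

    @property
    def reject(self) -> bool:
        return self.p < self.alpha


def _validate(pair: VariablePair) -> tuple[np.ndarray, np.ndarray]:
    x, y = np.asarray(pair.x, float), np.asarray(pair.y, float)
    if len(x) < 3:
        raise InsufficientDataError(f"n = {len(x)} < 3 for pair {pair.label!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError(f"zero variance in pair {pair.label!r}")
    return x, y


def fit_sma(pair: VariablePair, alpha: float = 0.05) -> SMAFit:
    """Fit the standardized major axis to a log-log variable pair."""
    x, y = _validate(pair)
    n = len(x)
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    b = sign * sy / sx
    a = float(np.mean(y) - b * np.mean(x))
    r2 = r * r

    B = stats.f.ppf(1 - alpha, 1, n - 2) * (1 - r2) / (n - 2)
    lims = (b * (np.sqrt(B + 1) - np.sqrt(B)), b * (np.sqrt(B + 1) + np.sqrt(B)))
    slope_ci = (min(lims), max(lims))

    resid = y - a - b * x
    s2 = float(resid @ resid) / (n - 2) if n > 2 else 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, n - 2)
    var_b = ((slope_ci[1] - slope_ci[0]) / (2 * tcrit)) ** 2
    var_a = s2 / n + np.mean(x) ** 2 * var_b
    half = tcrit * np.sqrt(var_a)
    return SMAFit(
        slope=float(b),
        intercept=a,
        r=r,
        r2=float(r2),
        n=n,
        alpha=alpha,
        slope_ci=(float(slope_ci[0]), float(slope_ci[1])),
        intercept_ci=(float(a - half), float(a + half)),
        label=pair.label,
    )


def test_slope(pair: VariablePair, b0: float, alpha: float = 0.05) -> SlopeHypothesisTest:
    """F test of whether the SMA slope equals ``b0``.

    Rotates the data into residual and axis scores for the null slope,
    u = y - b0*x and v = y + b0*x; under the null these are uncorrelated, so
    F = r_uv^2 (n-2) / (1 - r_uv^2) on (1, n-2) degrees of freedom.
    """
    x, y = _validate(pair)
    if b0 <= 0:
        warnings.warn(
            f"null slope b0 = {b0} is non-positive; allowed but unusual for "
            "log-log allometry",
            UserWarning,
            stacklevel=2,
        )
    n = len(x)
    r2 = _ruv2(x, y, b0)
    F = r2 * (n - 2) / max(1.0 - r2, np.finfo(float).tiny)
    p = float(stats.f.sf(F, 1, n - 2))
    return SlopeHypothesisTest(
        b0=b0, F=float(F), df=(1, n - 2), p=p, reject=p < alpha, alpha=alpha
    )


def ci_excludes(fit: SMAFit, b0: float) -> bool:
    """True iff ``b0`` lies strictly outside the slope confidence interval."""
    low, high = fit.slope_ci
    return bool(b0 < low or b0 > high)


def _ruv2(x: np.ndarray, y: np.ndarray, b: float) -> float:
    """Squared correlation between residual and axis scores at slope b."""
    u = y - b * x
    v = y + b * x
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        return 0.0
    c = np.corrcoef(u, v)[0, 1]
    return float(min(c * c, 1.0 - 1e-15))


def _cs_statistic(groups: list[tuple[np.ndarray, np.ndarray]], b: float) -> float:
    """Pooled likelihood-ratio statistic for a common slope b.

    Per group, twice the gap between the free bivariate-normal maximum and the
    profile likelihood at slope b is -n*log(1 - r_uv(b)^2); the pooled
    statistic is its sum over groups.
    """
    return float(sum(-len(x) * np.log1p(-_ruv2(x, y, b)) for x, y in groups))


def test_common_slope(
    pairs: list[VariablePair], alpha: float = 0.05
) -> CommonSlopeResult:
    """Likelihood-ratio test that all groups share one SMA slope.

    The pooled slope maximizes the summed per-group SMA profile
    log-likelihoods; the statistic 2*(sum logL_free - logL_common) is referred
    to chi-square with k-1 degrees of freedom.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("common-slope test needs at least 2 groups")
    fits = []
    for pair in pairs:
        try:
            fits.append(fit_sma(pair, alpha))
        except (DegenerateDataError, InsufficientDataError) as exc:
            raise type(exc)(f"group {pair.label!r}: {exc}") from None
    groups = [(np.asarray(p.x, float), np.asarray(p.y, float)) for p in pairs]
    slopes = [f.slope for f in fits]
    lo, hi = min(slopes), max(slopes)
    if np.isclose(lo, hi, rtol=0, atol=1e-12):
        b_c = lo
    else:
        res = optimize.minimize_scalar(
            lambda b: _cs_statistic(groups, b),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        b_c = float(res.x)
    statistic = max(_cs_statistic(groups, b_c), 0.0)
    df = len(pairs) - 1
    p = float(stats.chi2.sf(statistic, df))
    return CommonSlopeResult(
        b_common=b_c, statistic=statistic, df=df, p=p, group_fits=tuple(fits), alpha=alpha
    )


def test_elevation(
    pairs: list[VariablePair],
    alpha: float = 0.05,
    common: CommonSlopeResult | None = None,
) -> ElevationTestResult:
    """Wald test that all groups share one elevation at the common slope.

    Elevations are a_i = mean(y_i) - b_common * mean(x_i). Their covariance
    combines per-group residual variation about the common-slope axis with the
    shared uncertainty in the common slope itself (estimated from the observed
    curvature of the pooled profile likelihood), which induces positive
    covariance between elevations through the group means of x.
    """
    if len(pairs) < 2:
        raise InsufficientDataError("elevation test needs at least 2 groups")
    common = common if common is not None else test_common_slope(pairs, alpha)
    if common.reject:
        warnings.warn(
            f"common slope rejected (p = {common.p:.4g}); elevation comparison "
            "at a shared slope is questionable",
            UserWarning,
            stacklevel=2,
        )
    b = common.b_common
    groups = [(np.asarray(p.x, float), np.asarray(p.y, float)) for p in pairs]
    k = len(groups)
    ahat = np.array([np.mean(y) - b * np.mean(x) for x, y in groups])
    xbar = np.array([np.mean(x) for x, _ in groups])
    var_res = np.array(
        [np.var(y - b * x, ddof=1) / len(x) for x, y in groups]
    )

    # observed information of the pooled profile likelihood in b
    h = 1e-5 * max(1.0, abs(b))
    s0 = _cs_statistic(groups, b)
    info = (_cs_statistic(groups, b + h) - 2 * s0 + _cs_statistic(groups, b - h)) / (
        2 * h * h
    )
    var_b = 1.0 / info if info > 0 else 0.0

    V = np.diag(var_res) + var_b * np.outer(xbar, xbar)
    L = np.hstack([-np.ones((k - 1, 1)), np.eye(k - 1)])
    d = L @ ahat
    # pseudo-inverse: degenerate groups (zero residual variation, duplicated
    # groups) make the contrast covariance singular with d in its null space
    W = float(d @ np.linalg.pinv(L @ V @ L.T) @ d)
    p = float(stats.chi2.sf(W, k - 1))
    return ElevationTestResult(
        statistic=W,
        df=k - 1,
        p=p,
        b_common_used=b,
        elevations=tuple(ahat),
        alpha=alpha,
    )


def pairwise_elevation(
    pairs: list[VariablePair], alpha: float = 0.05
) -> dict[tuple[str, str], ElevationTestResult]:
    """Unadjusted 1-df elevation tests for every pair of groups.

    Each entry uses the two groups' own common slope. P values are reported
    raw: the repeated-testing trade-off is resolved in favour of power, with
    effect-size (CI) reporting alongside significance elsewhere.
    """
    out: dict[tuple[str, str], ElevationTestResult] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for i in range(len(pairs)):
            for j in range(i + 1, len(pairs)):
                out[(pairs[i].label, pairs[j].label)] = test_elevation(
                    [pairs[i], pairs[j]], alpha
                )
    return out
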
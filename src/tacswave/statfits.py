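"""Condition-curve fits and ANOVA-family hypothesis tests.

The sweep of a derived quantity (voltage range, field RMS, phase
difference) against the stimulation phase condition theta is summarized by
competing least-squares fits: a line ``y = a1*theta + b`` and a fixed-period
sinusoid ``y = a0 + a1*cos(w*theta) + b1*sin(w*theta)`` with one period per
360 degrees of theta, which makes the sinusoid fit linear in its
coefficients.  Group comparisons use the Kruskal-Wallis rank test, the
Brown-Forsythe spread test, and the Watson-Williams test for circular data;
all three are computed from their defining formulas with reference
distributions from scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sst

__all__ = [
    "CurveFit",
    "TestResult",
    "fit_condition_curve",
    "adjusted_r2",
    "kruskal_wallis",
    "brown_forsythe",
    "watson_williams",
]


@dataclass(frozen=True)
class CurveFit:
    kind: str
    coefficients: dict
    sse: float
    r_squared: float
    r_squared_adj: float
    n: int

    def __post_init__(self):
        if self.sse < -1e-12:
            raise ValueError("SSE must be nonnegative")


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: tuple
    p_value: float
    warning: str | None = None


def adjusted_r2(sse: float, sst: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (SSE/SST) * (n-1)/(n-p-1).

    ``p`` counts non-intercept regressors (1 for the line, 2 for the
    fixed-period sinusoid).
    """
    if sst <= 0:
        raise ValueError("SST must be positive")
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")
    return 1.0 - (sse / sst) * (n - 1) / (n - p - 1)


def fit_condition_curve(theta_deg, y, kind: str = "sinusoid") -> CurveFit:
    """Least-squares condition-curve fit over the phase sweep.

    kind="linear": ``y = a1*theta + b``.  kind="sinusoid":
    ``y = a0 + a1*cos(theta) + b1*sin(theta)`` with the angular frequency
    fixed to one period per 360 degrees of the condition axis.
    """
    theta = np.asarray(theta_deg, dtype=float)
    y = np.asarray(y, dtype=float)
    if theta.shape != y.shape:
        raise ValueError("theta and y must have equal length")
    n = theta.size
    if kind == "linear":
        if n < 3:
            raise ValueError("linear fit needs >= 3 points")
        design = np.column_stack([theta, np.ones(n)])
        names = ["a1", "b"]
        p = 1
    elif kind == "sinusoid":
        if n < 4:
            raise ValueError("sinusoid fit needs >= 4 points")
        rad = np.radians(theta)
        design = np.column_stack([np.ones(n), np.cos(rad), np.sin(rad)])
        names = ["a0", "a1", "b1"]
        p = 2
    else:
        raise ValueError(f"unknown fit kind {kind!r}")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design (degenerate condition sweep)")
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    r2a = 1.0 if sst == 0 else adjusted_r2(sse, sst, n, p)
    return CurveFit(
        kind=kind,
        coefficients=dict(zip(names, (float(c) for c in coef))),
        sse=sse,
        r_squared=r2,
        r_squared_adj=r2a,
        n=n,
    )


def _check_groups(groups, min_size=1):
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(groups):
        if g.size < min_size:
            raise ValueError(f"group {i} has fewer than {min_size} values")
    return groups


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis rank H with tie correction; chi-square p-value.

    ``H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2``, divided by the tie
    correction ``1 - sum(t^3 - t)/(N^3 - N)``; df = k - 1.
    """
    groups = _check_groups(groups, min_size=1)
    k = len(groups)
    pooled = np.concatenate(groups)
    n_tot = pooled.size
    ranks = sst.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3.0 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    if tie == 0:  # every value identical
        return TestResult("kruskal-wallis", 0.0, (k - 1, n_tot - k), 1.0)
    h /= tie
    h = max(h, 0.0)
    p = float(sst.chi2.sf(h, k - 1))
    return TestResult("kruskal-wallis", float(h), (k - 1, n_tot - k), p)


def _oneway_f(groups):
    k = len(groups)
    n_tot = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df1, df2 = k - 1, n_tot - k
    if ss_within == 0:
        return (0.0 if ss_between == 0 else np.inf), df1, df2
    return (ss_between / df1) / (ss_within / df2), df1, df2


def brown_forsythe(groups) -> TestResult:
    """Spread comparison: one-way ANOVA on |x - median(group)|."""
    groups = _check_groups(groups, min_size=2)
    transformed = [np.abs(g - np.median(g)) for g in groups]
    f, df1, df2 = _oneway_f(transformed)
    p = float(sst.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return TestResult("brown-forsythe", float(f), (df1, df2), p)


def _mean_resultant_length(angles_rad):
    return float(np.abs(np.exp(1j * angles_rad).mean()))


def _kappa_from_rbar(rbar: float) -> float:
    # maximum-likelihood inversion of the von Mises A(kappa) = rbar
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups_deg) -> TestResult:
    """Watson-Williams multi-sample test for equal mean directions.

    ``F = K * (N-k) (sum R_i - R) / ((k-1)(N - sum R_i))`` where R_i and R
    are within-group and pooled resultant lengths and
    ``K = 1 + 3/(8 kappa)`` is the concentration correction with kappa
    estimated from the mean within-group resultant.  Valid for reasonably
    concentrated samples; a warning is attached when the weighted mean
    resultant falls below 0.45 or a group's mean direction is undefined.
    """
    groups = _check_groups(groups_deg, min_size=1)
    rads = [np.radians(g) for g in groups]
    k = len(rads)
    n_tot = sum(g.size for g in rads)
    note = None
    resultants = []
    for i, g in enumerate(rads):
        ri = g.size * _mean_resultant_length(g)
        if ri < 1e-12 * g.size:
            note = f"group {i} has an undefined mean direction (resultant ~ 0)"
        resultants.append(ri)
    sum_r = float(np.sum(resultants))
    pooled = np.concatenate(rads)
    big_r = n_tot * _mean_resultant_length(pooled)
    rbar_w = sum_r / n_tot
    if rbar_w < 0.45 and note is None:
        note = (
            f"weighted mean resultant length {rbar_w:.3f} < 0.45: "
            "the F approximation may be inaccurate"
        )
    if note is not None:
        warnings.warn(note, stacklevel=2)
    kappa = _kappa_from_rbar(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    df1, df2 = k - 1, n_tot - k
    denom = n_tot - sum_r
    if denom <= 0:  # all angles identical within groups
        f = 0.0 if sum_r - big_r <= 1e-12 else np.inf
    else:
        f = correction * df2 * (sum_r - big_r) / (df1 * denom)
    f = max(float(f), 0.0) if np.isfinite(f) else float(f)
    p = float(sst.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return TestResult("watson-williams", f, (df1, df2), p, warning=note)
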
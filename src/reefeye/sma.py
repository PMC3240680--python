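"""Standardized major axis (SMA) line fitting and allometric inference.

SMA is the symmetric bivariate line-fitting method standard in allometry:
the fitted slope has magnitude s_y/s_x (ratio of sample standard
deviations) signed by the Pearson correlation, and the line passes through
the bivariate centroid. On log-log axes a length-vs-mass isometry has slope
1/3, so testing the fitted slope against 0.333 is the isometry test used
for eye diameter against body mass.

This module provides:

* :func:`sma_fit` — point estimate, correlation, and exact slope CI,
* :func:`sma_slope_test` — test of a hypothesised slope b0 through the
  correlation between residual scores (y − b0·x) and axis scores
  (y + b0·x),
* :func:`sma_common_slope` — multi-group inference: a common slope by
  1-D profile-likelihood optimisation, a likelihood-ratio test of slope
  equality, intercepts recomputed at the common slope, a Wald contrast of
  those intercepts, and the implied size factor 10^Δintercept,
* :func:`fit_group_lines` — convenience driver over a species table, with
  named presets for the optical-ratio regressions (numerators like LD² are
  formed on the natural scale, then log10-transformed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import round_sig

__all__ = [
    "SMAFit",
    "SlopeTestResult",
    "CommonSlopeResult",
    "GroupLinesResult",
    "sma_fit",
    "sma_slope_test",
    "sma_common_slope",
    "fit_group_lines",
    "REGRESSION_PRESETS",
]

_EPS = 1e-12


class DegenerateDataError(ValueError):
    """Zero variance or too few points for a line fit."""


@dataclass
class SMAFit:
    """A fitted SMA line: slope = sign(r)·s_y/s_x through the centroid."""

    n: int
    slope: float
    intercept: float
    r: float
    slope_ci_low: float
    slope_ci_high: float
    confidence: float
    mean_x: float
    mean_y: float
    intercept_ci_low: float = math.nan
    intercept_ci_high: float = math.nan


@dataclass
class SlopeTestResult:
    """Two-sided test of a hypothesised SMA slope b0."""

    b0: float
    statistic: float
    df: int
    p_value: float


@dataclass
class CommonSlopeResult:
    """Multi-group SMA: slope equality, common slope, intercept contrast."""

    groups: list[str]
    fits: dict[str, SMAFit]
    slope_equality_stat: float
    slope_equality_df: int
    slope_equality_p: float
    b_common: float
    var_b_common: float
    intercepts: dict[str, float]  # at b_common
    intercept_stat: float
    intercept_df: int
    intercept_p: float

    def size_factor(self, a: str, b: str) -> float:
        """10^(intercept_a − intercept_b): the ratio of fitted y at fixed x."""
        return 10.0 ** (self.intercepts[a] - self.intercepts[b])


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise DegenerateDataError(f"need n >= 3 points, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    return x, y


def sma_fit(x: Sequence[float], y: Sequence[float],
            confidence: float = 0.95) -> SMAFit:
    """Fit a standardized major axis line to (x, y).

    slope = sign(r) · s_y / s_x, intercept = ȳ − slope·x̄. The slope CI uses
    the exact pivot B = F(1, n−2; confidence) · (1−r²)/(n−2) with bounds
    slope·(√(B+1) ± √B).
    """
    x, y = _validate_xy(x, y)
    n = x.size
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    r = float(np.corrcoef(x, y)[0, 1])
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    mean_x, mean_y = float(np.mean(x)), float(np.mean(y))
    intercept = mean_y - slope * mean_x

    fcrit = stats.f.ppf(confidence, 1, n - 2)
    B = fcrit * (1.0 - r * r) / (n - 2)
    lo = slope * (math.sqrt(B + 1.0) - math.sqrt(B))
    hi = slope * (math.sqrt(B + 1.0) + math.sqrt(B))
    if lo > hi:
        lo, hi = hi, lo

    # elevation (intercept) CI: Var(â) = s²_z/n + x̄²·Var(b̂), where
    # z = y − b̂·x are residual scores and Var(b̂) ≈ b̂²·(1−r²)/(n−2)
    s2_z = float(np.var(y - slope * x, ddof=1))
    var_b = slope * slope * (1.0 - r * r) / (n - 2)
    se_a = math.sqrt(s2_z / n + mean_x * mean_x * var_b)
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 2)
    return SMAFit(n=n, slope=slope, intercept=intercept, r=r,
                  slope_ci_low=lo, slope_ci_high=hi, confidence=confidence,
                  mean_x=mean_x, mean_y=mean_y,
                  intercept_ci_low=intercept - tcrit * se_a,
                  intercept_ci_high=intercept + tcrit * se_a)


def _residual_axis_corr(x: np.ndarray, y: np.ndarray, b: float) -> float:
    """Correlation between residual scores y−b·x and axis scores y+b·x."""
    u = y - b * x
    v = y + b * x
    su, sv = float(np.std(u, ddof=1)), float(np.std(v, ddof=1))
    scale = max(float(np.std(y, ddof=1)), 1e-300)
    if su < _EPS * scale or sv < _EPS * scale:
        # data exactly on the tested line (or its mirror): no residual signal
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


def sma_slope_test(x: Sequence[float], y: Sequence[float],
                   b0: float) -> SlopeTestResult:
    """Two-sided test of H0: SMA slope = b0.

    Under H0 the residual scores u = y − b0·x and axis scores v = y + b0·x
    are uncorrelated; the statistic is t = r_uv·√((n−2)/(1−r_uv²)) with
    n−2 degrees of freedom. At b0 equal to the fitted slope r_uv = 0 and
    p = 1; for exactly collinear data and b0 ≠ slope the statistic is
    infinite and p = 0.
    """
    x, y = _validate_xy(x, y)
    if b0 == 0:
        raise ValueError("b0 = 0 leaves the SMA orientation undefined")
    n = x.size
    u = y - b0 * x
    v = y + b0 * x
    su, sv = float(np.std(u, ddof=1)), float(np.std(v, ddof=1))
    if su == 0.0 or sv == 0.0:
        # data exactly on the line y = b0·x + c (or its mirror): r_uv is 0/0;
        # the fitted slope equals ±b0, so the self-test limit applies
        return SlopeTestResult(b0=b0, statistic=0.0, df=n - 2, p_value=1.0)
    r_uv = float(np.corrcoef(u, v)[0, 1])
    denom = 1.0 - r_uv * r_uv
    if denom <= _EPS:
        return SlopeTestResult(b0=b0, statistic=math.inf, df=n - 2,
                               p_value=0.0)
    t = r_uv * math.sqrt((n - 2) / denom)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SlopeTestResult(b0=b0, statistic=t, df=n - 2, p_value=min(p, 1.0))


def _common_slope_objective(groups: list[tuple[np.ndarray, np.ndarray]],
                            b: float) -> float:
    """−2·log likelihood-ratio profile: Σ n_k · ln(1 − r²_uv,k(b))·(−1)."""
    total = 0.0
    for x, y in groups:
        r = _residual_axis_corr(x, y, b)
        r2 = min(r * r, 1.0 - 1e-15)
        total += -x.size * math.log1p(-r2)
    return total


def sma_common_slope(groups: Mapping[str, tuple[Sequence[float], Sequence[float]]],
                     confidence: float = 0.95) -> CommonSlopeResult:
    """Common-slope SMA inference across ≥ 2 groups.

    The common slope b̂ minimises the profile statistic
    Σ_k n_k·(−ln(1 − r²_uv,k(b))), where r_uv,k(b) is group k's correlation
    between residual and axis scores at slope b; at each group's own SMA
    slope its term vanishes, so the minimised value is the likelihood-ratio
    statistic for slope equality, referred to χ² with k−1 df.

    Intercepts are recomputed at b̂ as ȳ_k − b̂·x̄_k, and contrasted with a
    Wald statistic on the group means of the residual scores z = y − b̂·x,
    whose variance includes the residual-variance/n_k term plus the
    slope-uncertainty term x̄_k²·Var(b̂); Var(b̂) comes from the curvature of
    the profile statistic at its minimum.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    data = []
    fits: dict[str, SMAFit] = {}
    for lab in labels:
        x, y = _validate_xy(*groups[lab])
        data.append((x, y))
        fits[lab] = sma_fit(x, y, confidence)

    slopes = np.array([fits[lab].slope for lab in labels])
    if not (np.all(slopes > 0) or np.all(slopes < 0)):
        raise ValueError("group slopes differ in sign; no common SMA orientation")
    sgn = math.copysign(1.0, slopes[0])
    mags = np.abs(slopes)

    f = lambda b: _common_slope_objective(data, sgn * b)  # noqa: E731
    lo, hi = float(mags.min()), float(mags.max())
    width = 1.0
    while True:
        width *= 2.0
        blo, bhi = lo / width, hi * width
        res = optimize.minimize_scalar(
            f, bounds=(blo, bhi), method="bounded",
            options={"xatol": 1e-12 + 1e-10 * hi},
        )
        b_hat = float(res.x)
        if blo * 1.001 < b_hat < bhi / 1.001 or width > 1e6:
            break
    if width > 1e6 and not (blo * 1.001 < b_hat < bhi / 1.001):
        raise RuntimeError("common-slope optimisation failed to bracket")

    b_common = sgn * b_hat
    lr = max(f(b_hat), 0.0)
    k = len(labels)
    slope_p = float(stats.chi2.sf(lr, k - 1)) if lr > 0 else 1.0

    # curvature of the −2logΛ profile → Var(b̂) ≈ 2 / f''(b̂)
    h = 1e-4 * b_hat
    f2 = (f(b_hat + h) - 2.0 * f(b_hat) + f(b_hat - h)) / (h * h)
    var_b = 2.0 / f2 if f2 > 0 else math.inf

    intercepts: dict[str, float] = {}
    z_means, z_vars = [], []
    for lab, (x, y) in zip(labels, data):
        z = y - b_common * x
        intercepts[lab] = float(np.mean(z))
        resid_var = float(np.var(z, ddof=1))
        z_means.append(float(np.mean(z)))
        z_vars.append(resid_var / x.size + np.mean(x) ** 2 * var_b)
    z_means_arr = np.array(z_means)
    # floor keeps exactly-collinear groups (zero residual variance) finite
    w = 1.0 / np.maximum(np.array(z_vars), 1e-300)
    zbar = float(np.sum(w * z_means_arr) / np.sum(w))
    wald = float(np.sum(w * (z_means_arr - zbar) ** 2))
    int_p = float(stats.chi2.sf(wald, k - 1)) if wald > 0 else 1.0

    return CommonSlopeResult(
        groups=labels, fits=fits,
        slope_equality_stat=lr, slope_equality_df=k - 1,
        slope_equality_p=slope_p,
        b_common=b_common, var_b_common=var_b,
        intercepts=intercepts,
        intercept_stat=wald, intercept_df=k - 1, intercept_p=int_p,
    )


# ---------------------------------------------------------------------------
# Species-table driver

#: named (x, y) variable presets as products of natural-scale trait powers.
#: Composite regressors (LD², ED·AL, ...) are formed on the natural scale
#: and then log10-transformed, so the numerator of each optical ratio is
#: regressed against its denominator without size-dependent bias.
REGRESSION_PRESETS: dict[str, dict[str, tuple[tuple[str, int], ...]]] = {
    "eye_size": {"x": (("body_mass", 1),), "y": (("ed", 1),)},
    "opt_morph1": {"x": (("ed", 1), ("al", 1)), "y": (("ld", 2),)},
    "opt_morph2": {"x": (("ed", 1), ("al", 1)), "y": (("pdmin", 2),)},
    "opt_morph3": {"x": (("ed", 1), ("pdmax", 1)),
                   "y": (("ld", 1), ("pdmin", 1))},
    "pupil_shape": {"x": (("pdmax", 1),), "y": (("pdmin", 1),)},
    "lens_vs_pupil": {"x": (("pdmax", 1),), "y": (("ld", 1),)},
}


def _log_product(species: pd.DataFrame,
                 factors: tuple[tuple[str, int], ...]) -> np.ndarray:
    """log10 of a product of trait powers, rounded to 4 significant figures."""
    prod = np.ones(len(species))
    for col, power in factors:
        prod = prod * species[col].to_numpy(dtype=float) ** power
    return np.array([round_sig(math.log10(v), 4) for v in prod])


@dataclass
class GroupLinesResult:
    """Per-class, pooled, and common-slope SMA fits for one trait pair."""

    x_label: str
    y_label: str
    pooled: SMAFit
    common: CommonSlopeResult
    pooled_slope_test: SlopeTestResult | None = None
    group_slope_tests: dict[str, SlopeTestResult] = field(default_factory=dict)


def fit_group_lines(species: pd.DataFrame,
                    preset: str | None = None,
                    x: tuple[tuple[str, int], ...] | None = None,
                    y: tuple[tuple[str, int], ...] | None = None,
                    by: str = "diel_class",
                    exclude_anguilliform: bool = False,
                    anguilliform_families: frozenset[str] | None = None,
                    b0: float | None = None,
                    confidence: float = 0.95) -> GroupLinesResult:
    """Fit SMA lines per diel class, pooled, and with a common slope.

    Operates on a natural-scale species table (:func:`~reefeye.core_data.
    species_means` output). Variables are given either as a ``preset`` name
    (see :data:`REGRESSION_PRESETS`) or as explicit products of trait
    powers. ``b0`` adds an isometry-style slope test on the pooled data and
    each group.
    """
    if preset is not None:
        spec = REGRESSION_PRESETS[preset]
        x, y = spec["x"], spec["y"]
    if x is None or y is None:
        raise ValueError("provide a preset or explicit x and y factors")

    tab = species
    if exclude_anguilliform:
        from .core_data import ANGUILLIFORM_FAMILIES
        fams = anguilliform_families or ANGUILLIFORM_FAMILIES
        tab = tab[~tab["family"].isin(fams)]

    lx = _log_product(tab, x)
    ly = _log_product(tab, y)
    labels = tab[by].to_numpy()

    groups = {
        lab: (lx[labels == lab], ly[labels == lab])
        for lab in pd.unique(labels)
    }
    pooled = sma_fit(lx, ly, confidence)
    common = sma_common_slope(groups, confidence)

    def _fmt(factors: tuple[tuple[str, int], ...]) -> str:
        return "*".join(c if p == 1 else f"{c}^{p}" for c, p in factors)

    result = GroupLinesResult(x_label=_fmt(x), y_label=_fmt(y),
                              pooled=pooled, common=common)
    if b0 is not None:
        result.pooled_slope_test = sma_slope_test(lx, ly, b0)
        result.group_slope_tests = {
            lab: sma_slope_test(gx, gy, b0)
            for lab, (gx, gy) in groups.items()
        }
    return result
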
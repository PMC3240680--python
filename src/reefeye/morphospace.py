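"""Correlation-matrix PCA morphospace, size diagnostics, MANOVA, hulls.

Log-scale eye traits are so tightly correlated that the first principal
component of their correlation matrix is a size axis — its scores track
the log geometric mean of the traits almost perfectly — while the
remaining components describe shape alone. The module provides:

* :func:`pca_correlation` — PCA of the Pearson correlation matrix with a
  deterministic loading-sign convention,
* :func:`size_axis_report` — per-axis SMA regression of scores on the
  log10 geometric mean of the input traits (R² and correlation p),
* :func:`manova_two_groups` — Wilks' lambda with Rao's F approximation
  (exact for two groups), agreeing with the Hotelling T² route,
* :func:`hull_occupancy` — minimum convex polygons per class in a 2-D
  score plane and boundary-inclusive point-in-polygon tests of the
  opposite class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Point, Polygon

from .sma import sma_fit

__all__ = [
    "PCAResult",
    "ManovaResult",
    "HullOccupancy",
    "pca_correlation",
    "size_axis_report",
    "manova_two_groups",
    "hull_occupancy",
    "THREE_TRAIT_SET",
    "FIVE_TRAIT_SET",
]

#: the two trait presets used throughout: eyeball geometry only, or with pupils
THREE_TRAIT_SET: tuple[str, ...] = ("log_ed", "log_al", "log_ld")
FIVE_TRAIT_SET: tuple[str, ...] = (
    "log_ed", "log_al", "log_ld", "log_pdmax", "log_pdmin"
)

#: floor used when reporting vanishing p-values
P_FLOOR = 1e-15


def format_p(p: float) -> str:
    """Human-readable p; values below representable precision as '< 1e-15'."""
    return f"< {P_FLOOR:g}" if p < P_FLOOR else f"{p:.3g}"


@dataclass
class PCAResult:
    variables: list[str]
    eigenvalues: np.ndarray  # descending; sums to len(variables)
    loadings: np.ndarray  # columns are unit-norm eigenvectors
    scores: np.ndarray  # n × p, standardized variables projected
    pct_variance: np.ndarray  # sums to 100


def pca_correlation(table: pd.DataFrame,
                    variables: Sequence[str]) -> PCAResult:
    """PCA of the Pearson correlation matrix of the selected columns.

    Variables are standardized (mean 0, sd 1 with ddof=1) and projected on
    the eigenvectors of their correlation matrix. Loading signs are fixed
    deterministically: each column is flipped so its largest-magnitude
    entry is positive (eigenvector signs are otherwise arbitrary, so
    comparisons with published loadings are made up to a global sign per
    axis).
    """
    variables = list(variables)
    if len(variables) < 2:
        raise ValueError("need at least 2 variables")
    X = table[variables].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    if np.isnan(X).any():
        raise ValueError("missing values in PCA input")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValueError(f"constant variable(s) {const}: correlation undefined")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    scores = Z @ eigvec
    return PCAResult(
        variables=variables,
        eigenvalues=eigval,
        loadings=eigvec,
        scores=scores,
        pct_variance=100.0 * eigval / p,
    )


def size_axis_report(pca: PCAResult, table: pd.DataFrame) -> pd.DataFrame:
    """Association of each PC axis with overall size.

    Size is the log10 geometric mean of the traits entering the PCA, i.e.
    the row mean of the log columns. Per axis, an SMA regression of scores
    on size is summarised by R² (the squared Pearson correlation) and the
    two-sided p of that correlation. Axes beyond the first should show
    R² ≈ 0: they are shape axes.
    """
    gm = table[pca.variables].to_numpy(dtype=float).mean(axis=1)
    rows = []
    for j in range(pca.scores.shape[1]):
        s = pca.scores[:, j]
        r, p = stats.pearsonr(gm, s)
        fit = sma_fit(gm, s)
        rows.append({
            "axis": j + 1,
            "slope": fit.slope,
            "r_squared": float(r) ** 2,
            "p_value": float(p),
        })
    return pd.DataFrame(rows)


@dataclass
class ManovaResult:
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float


def manova_two_groups(scores: np.ndarray,
                      labels: Sequence[str]) -> ManovaResult:
    """One-way MANOVA (Wilks' lambda, Rao's F) on multivariate scores.

    Built for the two-group case on two shape axes (where Rao's
    approximation is exact and equivalent to Hotelling's T²), but valid
    for any number of groups/responses with non-singular within-group
    scatter.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be a 2-D array")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    g = classes.size
    n, p = Y.shape
    if g < 2:
        raise ValueError("need at least two groups")
    for c in classes:
        if (labels == c).sum() <= p:
            raise ValueError(f"group {c!r} needs more than {p} members")

    grand = Y.mean(axis=0)
    T = (Y - grand).T @ (Y - grand)
    W = np.zeros((p, p))
    for c in classes:
        sub = Y[labels == c]
        W += (sub - sub.mean(axis=0)).T @ (sub - sub.mean(axis=0))
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular within-group scatter matrix")
    lam = float(np.exp(logdet_w - logdet_t))

    q = g - 1
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    w_ = n - 1 - (p + g) / 2.0
    df1 = p * q
    df2 = w_ * t - (p * q - 2.0) / 2.0
    lam_t = lam ** (1.0 / t)
    f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(stats.f.sf(f_stat, df1, df2))
    return ManovaResult(wilks_lambda=lam, f_statistic=float(f_stat),
                        df1=df1, df2=df2, p_value=p_val)


@dataclass
class HullOccupancy:
    """Convex hulls per class and opposite-class outsiders.

    ``hulls[label]`` holds hull vertices in counter-clockwise order;
    ``outside[label]`` is a boolean array over that class's own points
    marking which fall strictly outside the *other* class's hull
    (boundary counts as inside). Two-class use only.
    """

    hulls: dict[str, np.ndarray]
    outside: dict[str, np.ndarray]
    areas: dict[str, float]


def hull_occupancy(points_by_class: Mapping[str, np.ndarray]) -> HullOccupancy:
    """Minimum convex polygons per class and cross-class occupancy.

    Each class needs ≥ 3 non-collinear 2-D points; a collinear class
    raises. For exactly two classes, each class's points are tested
    against the other class's hull.
    """
    hulls: dict[str, np.ndarray] = {}
    polys: dict[str, Polygon] = {}
    areas: dict[str, float] = {}
    for lab, pts in points_by_class.items():
        pts = np.asarray(pts, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"class {lab!r}: expected n×2 points")
        if pts.shape[0] < 3:
            raise ValueError(f"class {lab!r}: need at least 3 points")
        try:
            hull = ConvexHull(pts)
        except QhullError as exc:
            raise ValueError(f"class {lab!r}: degenerate (collinear) "
                             f"point set") from exc
        verts = pts[hull.vertices]  # counter-clockwise in 2-D
        hulls[lab] = verts
        polys[lab] = Polygon(verts)
        areas[lab] = float(hull.volume)  # 2-D: "volume" is the area

    outside: dict[str, np.ndarray] = {}
    labs = list(points_by_class)
    if len(labs) == 2:
        for lab, other in (labs, labs[::-1]):
            pts = np.asarray(points_by_class[lab], dtype=float)
            poly = polys[other]
            outside[lab] = np.array(
                [not poly.covers(Point(*pt)) for pt in pts], dtype=bool
            )
    return HullOccupancy(hulls=hulls, outside=outside, areas=areas)
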
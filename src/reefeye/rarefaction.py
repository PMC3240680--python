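"""Morphological disparity on shape axes and the rarefaction diversity test.

Disparity of a diel class is the summed sample variance of its scores on
the shape axes (PCs 2–5) of the five-trait correlation PCA. Because the
diurnal class is much larger than the nocturnal one, the comparison is
rarefied: each iteration draws a diurnal subsample of the nocturnal size
without replacement, re-runs the correlation PCA on the combined
equal-size table, and records both classes' shape variances from that
iteration's own axes. The one-sided p-value uses the add-one permutation
convention,

    p = (1 + #{iterations with diurnal variance ≤ nocturnal variance})
        / (n_iterations + 1),

so it is never exactly zero and is reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphospace import FIVE_TRAIT_SET, PCAResult, pca_correlation

__all__ = ["RarefactionResult", "shape_variance", "rarefy_diversity"]

#: shape axes (0-based column slice of the score matrix): PCs 2–5
SHAPE_AXES = slice(1, 5)


def shape_variance(scores: np.ndarray, labels, cls: str,
                   axes: slice = SHAPE_AXES) -> float:
    """Summed sample variance of one class's scores on the shape axes."""
    labels = np.asarray(labels)
    sub = np.asarray(scores, dtype=float)[labels == cls][:, axes]
    if sub.shape[0] < 2:
        raise ValueError(f"class {cls!r} needs at least 2 members")
    return float(np.var(sub, axis=0, ddof=1).sum())


@dataclass
class RarefactionResult:
    n_iterations: int
    seed: int | None
    diurnal_variance: np.ndarray  # per iteration
    nocturnal_variance: np.ndarray  # per iteration
    observed: dict[str, float]  # full-data shape variances per class
    p_value: float
    quantiles: pd.DataFrame

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "observed": self.observed,
            "p_value": self.p_value,
            "diurnal_variance_mean": float(self.diurnal_variance.mean()),
            "nocturnal_variance_mean": float(self.nocturnal_variance.mean()),
        }


def _combined_shape_variances(X: np.ndarray, m: int) -> tuple[float, float]:
    """Shape variances of two stacked equal-size classes after corr-PCA.

    First m rows are nocturnal, last m diurnal. Returns (nocturnal,
    diurnal) summed score variance on PCs 2–5.
    """
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    R = (Z.T @ Z) / (X.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    scores = Z @ eigvec[:, order]
    noct = float(np.var(scores[:m, SHAPE_AXES], axis=0, ddof=1).sum())
    diur = float(np.var(scores[m:, SHAPE_AXES], axis=0, ddof=1).sum())
    return noct, diur


def rarefy_diversity(table: pd.DataFrame,
                     variables=FIVE_TRAIT_SET,
                     n_iter: int = 100_000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     label_col: str = "diel_class") -> RarefactionResult:
    """Rarefied comparison of diurnal vs nocturnal shape-space variance.

    Per iteration, draws as many diurnal species as there are nocturnal
    ones (uniformly, without replacement), re-runs the correlation PCA on
    the combined table, and records each class's shape variance on that
    iteration's PCs 2–5. Identical seeds and inputs give bit-identical
    distributions.
    """
    variables = list(variables)
    labels = table[label_col].to_numpy()
    X = table[variables].to_numpy(dtype=float)
    noct_idx = np.flatnonzero(labels == "nocturnal")
    diur_idx = np.flatnonzero(labels == "diurnal")
    m = noct_idx.size
    if m < 3:
        raise ValueError(f"need at least 3 nocturnal species, got {m}")
    if diur_idx.size < m:
        raise ValueError(
            f"diurnal count ({diur_idx.size}) smaller than nocturnal ({m})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    Xn = X[noct_idx]
    noct_var = np.empty(n_iter)
    diur_var = np.empty(n_iter)
    for i in range(n_iter):
        pick = rng.choice(diur_idx, size=m, replace=False)
        noct_var[i], diur_var[i] = _combined_shape_variances(
            np.vstack([Xn, X[pick]]), m
        )

    full: PCAResult = pca_correlation(table, variables)
    observed = {
        cls: shape_variance(full.scores, labels, cls)
        for cls in ("diurnal", "nocturnal")
    }
    p = (1.0 + np.sum(diur_var <= noct_var)) / (n_iter + 1.0)

    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    quantiles = pd.DataFrame({
        "quantile": qs,
        "diurnal_variance": np.quantile(diur_var, qs),
        "nocturnal_variance": np.quantile(noct_var, qs),
    })
    return RarefactionResult(
        n_iterations=n_iter, seed=seed,
        diurnal_variance=diur_var, nocturnal_variance=noct_var,
        observed=observed, p_value=float(p), quantiles=quantiles,
    )
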
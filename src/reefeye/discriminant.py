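"""Diel-class discriminant analysis: LDA, QDA, RDA, and FDA.

All four classifiers predict the diel activity class (nocturnal/diurnal)
from log eye traits with class priors equal to the training-set class
frequencies, and report resubstitution error (the same single proportions
the analysis compares across methods).

A single Gaussian engine underlies LDA, QDA, and RDA. The regularized
covariance of class k is a two-parameter blend (Friedman-style):

    S_k(λ)   = [(1−λ)·(n_k−1)·S_k + λ·(n−K)·S_pooled]
               / [(1−λ)·(n_k−1) + λ·(n−K)]
    S_k(λ,γ) = (1−γ)·S_k(λ) + γ·(tr S_k(λ)/p)·I

so λ = 1 (γ = 0) is exactly LDA (pooled covariance) and λ = 0 is exactly
QDA (class covariances). FDA is optimal scoring with a linear regression
basis: regress the class-indicator matrix on the traits, eigendecompose
the induced scoring problem, then classify in the resulting discriminant
variates with a pooled Gaussian rule — which coincides with LDA
predictions (the variates span LDA's canonical subspace).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DAResult",
    "da_fit_predict",
    "rda_lambda_scan",
    "misclassified_species",
    "consistently_misclassified",
    "DA_METHODS",
]

DA_METHODS = ("lda", "qda", "rda", "fda")


class RegularizationError(np.linalg.LinAlgError):
    """Covariance singular at the requested (lambda, gamma)."""


@dataclass
class DAResult:
    method: str
    variables: list[str]
    classes: list[str]
    priors: dict[str, float]
    lambda_: float | None
    gamma: float | None
    species_id: np.ndarray
    true_class: np.ndarray
    predicted_class: np.ndarray
    posteriors: np.ndarray  # n × K, rows sum to 1; columns follow `classes`

    @property
    def misclassified_fraction(self) -> float:
        return float(np.mean(self.predicted_class != self.true_class))

    @property
    def misclassified(self) -> list[str]:
        return sorted(self.species_id[self.predicted_class != self.true_class])


def _class_stats(X: np.ndarray, y: np.ndarray, classes: np.ndarray):
    n, p = X.shape
    K = classes.size
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    covs = []
    pooled = np.zeros((p, p))
    for c in classes:
        sub = X[y == c]
        dc = sub - sub.mean(axis=0)
        S = dc.T @ dc
        pooled += S
        covs.append(S / max(sub.shape[0] - 1, 1))
    pooled /= (n - K)
    counts = np.array([(y == c).sum() for c in classes])
    return means, np.stack(covs), pooled, counts


def _blend_cov(covs: np.ndarray, pooled: np.ndarray, counts: np.ndarray,
               n: int, lambda_: float, gamma: float) -> np.ndarray:
    """Per-class regularized covariances S_k(λ, γ)."""
    K, p, _ = covs.shape
    out = np.empty_like(covs)
    for k in range(K):
        w_k = (1.0 - lambda_) * (counts[k] - 1)
        w_p = lambda_ * (n - K)
        S = (w_k * covs[k] + w_p * pooled) / (w_k + w_p)
        if gamma > 0:
            S = (1.0 - gamma) * S + gamma * (np.trace(S) / p) * np.eye(p)
        out[k] = S
    return out


def _gaussian_log_posterior(X: np.ndarray, means: np.ndarray,
                            covs: np.ndarray, priors: np.ndarray,
                            classes: np.ndarray) -> np.ndarray:
    n, p = X.shape
    K = classes.size
    logp = np.empty((n, K))
    for k in range(K):
        sign, logdet = np.linalg.slogdet(covs[k])
        if sign <= 0:
            raise RegularizationError(
                f"covariance for class {classes[k]!r} is singular at the "
                f"requested regularization"
            )
        d = X - means[k]
        sol = np.linalg.solve(covs[k], d.T).T
        maha = np.einsum("ij,ij->i", d, sol)
        logp[:, k] = np.log(priors[k]) - 0.5 * logdet - 0.5 * maha
    return logp


def _posteriors_from_log(logp: np.ndarray) -> np.ndarray:
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    return w / w.sum(axis=1, keepdims=True)


def _fda_discriminants(X: np.ndarray, y: np.ndarray,
                       classes: np.ndarray) -> np.ndarray:
    """Optimal-scoring discriminant variates with a linear basis.

    Regress the class indicator matrix on [1, X]; the nontrivial
    eigenvectors of diag(1/n_k)·YᵀŶ give the optimal scores, and the
    fitted values mapped through them are the discriminant variates
    (n × (K−1)).
    """
    n, p = X.shape
    K = classes.size
    Y = np.zeros((n, K))
    for k, c in enumerate(classes):
        Y[y == c, k] = 1.0
    X1 = np.column_stack([np.ones(n), X])
    B, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    Yhat = X1 @ B
    counts = Y.sum(axis=0)
    # eigenproblem of diag(1/n_k)·YᵀŶ, symmetrized via a diag(sqrt(n_k))
    # similarity transform for a stable eigh
    D = np.sqrt(counts)
    Ms = (Y.T @ Yhat) / np.outer(D, D)
    theta2, U = np.linalg.eigh((Ms + Ms.T) / 2.0)
    order = np.argsort(theta2)[::-1]
    theta2, U = theta2[order], U[:, order]
    # drop the trivial direction (constant scores, eigenvalue 1) and any
    # null directions
    Theta = U / D[:, None]
    keep = []
    for j in range(K):
        scores_j = Theta[:, j]
        if np.allclose(scores_j, scores_j[0]):
            continue
        if theta2[j] < 1e-12:
            continue
        keep.append(j)
    keep = keep[: K - 1]
    return Yhat @ Theta[:, keep]


def da_fit_predict(table: pd.DataFrame,
                   variables: Sequence[str],
                   method: str = "lda",
                   lambda_: float | None = None,
                   gamma: float = 0.0,
                   label_col: str = "diel_class",
                   id_col: str = "species_id") -> DAResult:
    """Fit a discriminant classifier and predict on the same table.

    ``method`` is one of ``lda``, ``qda``, ``rda`` (requires ``lambda_``),
    or ``fda``. Priors are the class frequencies of the table. Posterior
    columns follow alphabetical class order; ties in the posterior break
    toward the alphabetically first class.
    """
    method = method.lower()
    if method not in DA_METHODS:
        raise ValueError(f"unknown method {method!r}")
    variables = list(variables)
    X = table[variables].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    ids = table[id_col].to_numpy()
    classes = np.array(sorted(pd.unique(y)))
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    counts = np.array([(y == c).sum() for c in classes])
    priors = counts / n

    if method == "rda":
        if lambda_ is None:
            raise ValueError("rda requires lambda_")
        lam = float(lambda_)
    elif method == "lda":
        lam = 1.0
    elif method == "qda":
        lam = 0.0
    else:
        lam = None  # fda

    if method == "fda":
        H = _fda_discriminants(X, y, classes)
        means, covs, pooled, _ = _class_stats(H, y, classes)
        covs_used = np.stack([pooled] * classes.size)
        logp = _gaussian_log_posterior(H, means, covs_used, priors, classes)
    else:
        means, covs, pooled, counts_ = _class_stats(X, y, classes)
        covs_used = _blend_cov(covs, pooled, counts_, n, lam, gamma)
        logp = _gaussian_log_posterior(X, means, covs_used, priors, classes)

    post = _posteriors_from_log(logp)
    pred = classes[np.argmax(post, axis=1)]
    return DAResult(
        method=method, variables=variables, classes=list(classes),
        priors={c: float(pr) for c, pr in zip(classes, priors)},
        lambda_=lam if method == "rda" else (lam if method in ("lda", "qda") else None),
        gamma=gamma if method == "rda" else None,
        species_id=ids, true_class=y, predicted_class=pred,
        posteriors=post,
    )


@dataclass
class LambdaScanResult:
    scan: pd.DataFrame  # columns: lambda, misclassified_fraction
    best_lambdas: list[float]  # all minimizers (plateaus included)
    best_fraction: float


def rda_lambda_scan(table: pd.DataFrame,
                    variables: Sequence[str],
                    lambdas: Iterable[float] | None = None,
                    gamma: float = 0.0,
                    **kwargs) -> LambdaScanResult:
    """Resubstitution error of RDA across a grid of lambdas.

    Default grid is 0 to 1 in steps of 0.01. The full set of minimizing
    lambdas is reported, since flat error plateaus are common.
    """
    if lambdas is None:
        lambdas = np.round(np.arange(0, 101) / 100.0, 2)
    rows = []
    for lam in lambdas:
        res = da_fit_predict(table, variables, method="rda",
                             lambda_=float(lam), gamma=gamma, **kwargs)
        rows.append({"lambda": float(lam),
                     "misclassified_fraction": res.misclassified_fraction})
    scan = pd.DataFrame(rows)
    best = scan["misclassified_fraction"].min()
    best_lams = scan.loc[
        scan["misclassified_fraction"] <= best + 1e-12, "lambda"
    ].tolist()
    return LambdaScanResult(scan=scan, best_lambdas=best_lams,
                            best_fraction=float(best))


def misclassified_species(result: DAResult) -> pd.DataFrame:
    """Stable sorted table of misclassified species with true/predicted."""
    bad = result.predicted_class != result.true_class
    out = pd.DataFrame({
        "species_id": result.species_id[bad],
        "true_class": result.true_class[bad],
        "predicted_class": result.predicted_class[bad],
    })
    return out.sort_values("species_id", kind="stable").reset_index(drop=True)


def consistently_misclassified(results: Iterable[DAResult]) -> list[str]:
    """Species misclassified by every result (intersection across methods)."""
    sets = [set(r.misclassified) for r in results]
    if not sets:
        return []
    common = set.intersection(*sets)
    return sorted(common)
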
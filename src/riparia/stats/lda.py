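"""Linear discriminant analysis with Gaussian equal-covariance posteriors.

The model stores per-class means, the pooled within-class covariance and
class priors; prediction applies the Bayes rule under the shared-covariance
Gaussian assumption and returns per-class posterior probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["LDAModel", "fit_lda", "predict_lda"]


@dataclass
class LDAModel:
    covariate_names: list[str]
    class_labels: list
    class_means: np.ndarray  # (n_classes, n_covariates)
    pooled_cov: np.ndarray  # (n_covariates, n_covariates)
    priors: np.ndarray  # (n_classes,)
    class_counts: np.ndarray  # (n_classes,)
    _cov_inv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.pooled_cov = np.asarray(self.pooled_cov, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        self.class_counts = np.asarray(self.class_counts)
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        k, p = self.class_means.shape
        if self.pooled_cov.shape != (p, p):
            raise ValueError("pooled covariance shape mismatch")
        if len(self.class_labels) != k:
            raise ValueError("labels/means mismatch")

    @property
    def cov_inv(self) -> np.ndarray:
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.pooled_cov)
        return self._cov_inv

    def to_json(self) -> str:
        return json.dumps(
            {
                "covariate_names": self.covariate_names,
                "class_labels": [str(c) for c in self.class_labels],
                "class_means": self.class_means.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "priors": self.priors.tolist(),
                "class_counts": self.class_counts.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LDAModel":
        d = json.loads(text)
        return cls(
            covariate_names=d["covariate_names"],
            class_labels=d["class_labels"],
            class_means=np.array(d["class_means"]),
            pooled_cov=np.array(d["pooled_cov"]),
            priors=np.array(d["priors"]),
            class_counts=np.array(d["class_counts"]),
        )


def fit_lda(X, y, priors: str = "empirical", names: Sequence[str] | None = None) -> LDAModel:
    """Fit the equal-covariance Gaussian classifier.

    ``priors`` is ``"empirical"`` (class frequencies, the default) or
    ``"uniform"``.  A near-singular pooled covariance is ridge-inflated by
    ``1e-8 * trace`` with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y)
    n, p = X.shape
    classes = list(np.unique(y))
    k = len(classes)
    if k < 2:
        raise ValueError("need at least two classes")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    means = np.empty((k, p))
    counts = np.empty(k, dtype=int)
    pooled = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xg = X[y == c]
        counts[i] = Xg.shape[0]
        means[i] = Xg.mean(axis=0)
        d = Xg - means[i]
        pooled += d.T @ d
    dof = n - k
    if dof <= 0:
        raise ValueError("not enough samples to estimate the pooled covariance")
    pooled /= dof

    # ridge fallback for collinear covariate stacks
    eps = 1e-8 * max(np.trace(pooled), 1e-300)
    if np.linalg.matrix_rank(pooled) < p or np.linalg.cond(pooled) > 1e12:
        warnings.warn("pooled covariance is ill-conditioned; applying ridge inflation", stacklevel=2)
        pooled = pooled + eps * np.eye(p)

    if priors == "empirical":
        pr = counts / counts.sum()
    elif priors == "uniform":
        pr = np.full(k, 1.0 / k)
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    return LDAModel(list(names), classes, means, pooled, pr, counts)


def predict_lda(model: LDAModel, X) -> np.ndarray:
    """Per-class posterior probabilities, shape (n, n_classes); rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"expected {model.class_means.shape[1]} covariates "
            f"({model.covariate_names}), got {X.shape[1]}"
        )
    inv = model.cov_inv
    # log p(x|k) + log prior, up to a shared constant
    logp = np.empty((X.shape[0], len(model.class_labels)))
    for i, mu in enumerate(model.class_means):
        d = X - mu
        logp[:, i] = -0.5 * np.einsum("ij,jk,ik->i", d, inv, d) + np.log(model.priors[i])
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    return post


def predict_lda_table(model: LDAModel, table: Mapping[str, np.ndarray]) -> np.ndarray:
    """Posteriors from a mapping of covariate name -> value array.

    Raises a schema error when a model covariate is missing from the table.
    """
    missing = [c for c in model.covariate_names if c not in table]
    if missing:
        raise KeyError(f"prediction input is missing model covariates: {missing}")
    X = np.column_stack([np.asarray(table[c], dtype=float).ravel() for c in model.covariate_names])
    return predict_lda(model, X)
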
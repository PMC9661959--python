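"""Wilks' Lambda and greedy forward covariate selection for discriminant models.

Wilks' Lambda is the ratio det(W)/det(T) of the pooled within-class to the
total cross-product matrix over a covariate subset; smaller values mean
stronger class separation.  The forward selector adds, at each step, the
candidate minimising the partial Lambda, gated by a partial-F significance
test — the classical stepwise discriminant procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["wilks_lambda", "greedy_wilks_forward", "ForwardStep", "DegenerateCovariatesError"]


class DegenerateCovariatesError(ValueError):
    """Total scatter matrix is singular: covariates are linearly dependent."""


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (W) and total (T) cross-product matrices."""
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        d = Xg - Xg.mean(axis=0)
        W += d.T @ d
    return W, T


def wilks_lambda(X, y, subset: Sequence[int] | None = None) -> float:
    """Wilks' Lambda det(W)/det(T) over the given covariate columns.

    Parameters
    ----------
    X : array-like, shape (n, p)
    y : array-like of class labels, length n
    subset : column indices to use; all columns when None.

    Returns Lambda in [0, 1]; 1 iff all class means coincide on the subset.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(y)
    if subset is not None:
        X = X[:, list(subset)]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    W, T = _scatter_matrices(X, y)
    det_t = np.linalg.det(T)
    if not np.isfinite(det_t) or abs(det_t) < np.finfo(float).tiny * max(1.0, np.trace(T) ** T.shape[0]):
        raise DegenerateCovariatesError("total scatter matrix is singular over the subset")
    lam = float(np.linalg.det(W) / det_t)
    # guard tiny negative round-off
    return min(max(lam, 0.0), 1.0)


@dataclass(frozen=True)
class ForwardStep:
    """One accepted step of the forward selection."""

    covariate: str
    wilks: float
    partial_f: float
    p_value: float


def greedy_wilks_forward(
    X,
    y,
    p_enter: float = 0.05,
    names: Sequence[str] | None = None,
) -> list[ForwardStep]:
    """Stepwise forward covariate selection on the Wilks' Lambda criterion.

    At each step every remaining candidate is scored by the Wilks' Lambda of
    the selected set plus that candidate; the minimiser enters if its
    partial-F test has p-value below ``p_enter``.  Candidates that make the
    total scatter singular (e.g. duplicates of selected covariates) are
    skipped with a warning.

    Returns the ordered list of accepted :class:`ForwardStep`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    n, p = X.shape
    g = np.unique(y).size
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match number of columns")

    selected: list[int] = []
    steps: list[ForwardStep] = []
    lambda_prev = 1.0
    remaining = list(range(p))
    while remaining:
        k = len(selected)
        df2 = n - g - k
        if df2 <= 0:
            break
        best = None
        for j in remaining:
            try:
                lam = wilks_lambda(X, y, selected + [j])
            except DegenerateCovariatesError:
                warnings.warn(
                    f"candidate {names[j]!r} makes the scatter matrix singular; skipped",
                    stacklevel=2,
                )
                continue
            if best is None or lam < best[1]:
                best = (j, lam)
        if best is None:
            break
        j, lam = best
        partial = lam / lambda_prev if lambda_prev > 0 else 0.0
        partial = min(max(partial, 0.0), 1.0)
        if partial <= 0.0:
            f_stat, p_val = np.inf, 0.0
        else:
            f_stat = (1.0 - partial) / partial * df2 / (g - 1)
            p_val = float(sps.f.sf(f_stat, g - 1, df2))
        if p_val >= p_enter:
            break
        selected.append(j)
        remaining.remove(j)
        steps.append(ForwardStep(names[j], lam, float(f_stat), p_val))
        lambda_prev = lam
    return steps
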
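"""Proportional-odds (cumulative logit) ordinal regression by maximum likelihood.

The model for an ordinal outcome y in {0, ..., K-1} with predictors x is

    P(y <= j) = logistic(alpha_{j+1} - x @ beta),   j = 0..K-2

with strictly increasing thresholds alpha.  Thresholds are optimised in a
log-increment parameterisation so the ordering constraint always holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

__all__ = ["OrdinalFit", "fit_proportional_odds", "OrdinalConvergenceError"]


class OrdinalConvergenceError(RuntimeError):
    """Optimiser failed, typically under complete separation or a degenerate outcome."""


@dataclass
class OrdinalFit:
    thresholds: np.ndarray  # (K-1,), strictly increasing
    coefficients: np.ndarray  # (p,)
    coefficient_names: list[str]
    log_likelihood: float
    aic: float
    n: int
    n_categories: int

    def category_probs(self, X) -> np.ndarray:
        """Per-observation category probabilities, rows summing to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        eta = X @ self.coefficients
        cum = expit(self.thresholds[None, :] - eta[:, None])  # (n, K-1)
        cum = np.concatenate([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))], axis=1)
        return np.diff(cum, axis=1)


def _unpack(theta: np.ndarray, k: int, p: int):
    a = theta[: k - 1]
    alphas = np.empty(k - 1)
    alphas[0] = a[0]
    if k > 2:
        alphas[1:] = a[0] + np.cumsum(np.exp(a[1:]))
    beta = theta[k - 1 :]
    return alphas, beta


def _nll_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, k: int):
    n, p = X.shape
    alphas, beta = _unpack(theta, k, p)
    eta = X @ beta
    # z2 = alpha_{y+1} - eta (upper), z1 = alpha_y - eta (lower)
    big = 1e30
    a_ext = np.concatenate([[-big], alphas, [big]])
    z2 = a_ext[y + 1] - eta
    z1 = a_ext[y] - eta
    F2, F1 = expit(z2), expit(z1)
    d = np.clip(F2 - F1, 1e-300, None)
    nll = -np.sum(np.log(d))

    f2 = F2 * (1 - F2)
    f1 = F1 * (1 - F1)
    # gradient wrt beta: sum_i (f2 - f1)/d * x_i
    g_beta = ((f2 - f1) / d) @ X
    # gradient wrt each raw threshold alpha_j
    g_alpha = np.zeros(k - 1)
    for j in range(1, k):  # threshold alpha_j is upper bound of category j-1, lower of j
        idx_up = y == (j - 1)
        idx_lo = y == j
        g = -np.sum(f2[idx_up] / d[idx_up]) + np.sum(f1[idx_lo] / d[idx_lo])
        g_alpha[j - 1] = g
    # chain rule to log-increment parameterisation
    g_a = np.zeros(k - 1)
    g_a[0] = g_alpha.sum()
    if k > 2:
        a = theta[: k - 1]
        for m in range(1, k - 1):
            g_a[m] = np.exp(a[m]) * g_alpha[m:].sum()
    return nll, np.concatenate([g_a, g_beta])


def fit_proportional_odds(y, X, names: Sequence[str] | None = None) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit.

    ``y`` holds ordinal codes 0..K-1 (at least two categories observed);
    ``X`` is the predictor matrix without an intercept column.
    """
    y = np.asarray(y, dtype=int).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    cats = np.unique(y)
    if cats.size < 2:
        raise OrdinalConvergenceError("outcome has a single observed category")
    # recode to consecutive 0..K-1 for the likelihood
    recode = {c: i for i, c in enumerate(cats)}
    y_rec = np.array([recode[v] for v in y])
    k = cats.size
    if names is None:
        names = [f"x{j}" for j in range(p)]

    # start at intercept-only cumulative logits
    cum = np.cumsum(np.bincount(y_rec, minlength=k))[:-1] / n
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    alpha0 = np.log(cum / (1 - cum))
    theta0 = np.zeros(k - 1 + p)
    theta0[0] = alpha0[0]
    if k > 2:
        theta0[1 : k - 1] = np.log(np.clip(np.diff(alpha0), 1e-6, None))

    res = minimize(
        _nll_grad,
        theta0,
        args=(X, y_rec, k),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.status != 2:  # status 2: precision loss near optimum
        raise OrdinalConvergenceError(f"optimiser failed: {res.message}")
    alphas, beta = _unpack(res.x, k, p)
    if np.any(np.abs(beta) > 50) or np.any(np.abs(alphas) > 50):
        raise OrdinalConvergenceError("fit diverged; data may be completely separated")
    ll = -float(res.fun)
    n_par = k - 1 + p
    return OrdinalFit(
        thresholds=alphas,
        coefficients=beta,
        coefficient_names=list(names),
        log_likelihood=ll,
        aic=2 * n_par - 2 * ll,
        n=n,
        n_categories=k,
    )
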
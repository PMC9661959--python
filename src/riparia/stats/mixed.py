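"""Random-intercept linear mixed model, backed by statsmodels MixedLM.

Fits are maximum likelihood (not REML) so that AIC values are comparable
across models with different fixed effects on the same data.  The optimiser
is unreliable when the group variance estimate sits on the zero boundary,
so the fit is checked against the boundary (OLS) likelihood and the better
model is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MixedFit", "fit_random_intercept_lm"]


@dataclass
class MixedFit:
    fixed_names: list[str]
    fixed_coefficients: np.ndarray
    fixed_se: np.ndarray
    random_intercept_var: float
    residual_var: float
    aic: float
    log_likelihood: float
    n: int

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.fixed_coefficients, "std_error": self.fixed_se},
            index=self.fixed_names,
        )


def _ols_boundary_fit(y: np.ndarray, exog: np.ndarray, fixed_names, k_par: int) -> MixedFit:
    """ML fit at the zero-group-variance boundary (plain OLS)."""
    n, p1 = exog.shape
    coef, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ coef
    sigma2 = float(resid @ resid) / n
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
    xtx_inv = np.linalg.inv(exog.T @ exog)
    se = np.sqrt(np.diag(xtx_inv) * sigma2 * n / max(n - p1, 1))
    return MixedFit(fixed_names, coef, se, 0.0, sigma2, 2 * k_par - 2 * ll, ll, n)


def fit_random_intercept_lm(y, X_fixed, group, names: Sequence[str] | None = None) -> MixedFit:
    """Linear model with a random intercept per group, fitted by ML.

    ``X_fixed`` excludes the intercept (added internally).  With a single
    group the model still fits but the random variance is reported as 0
    with a warning.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    y = np.asarray(y, dtype=float).ravel()
    group = np.asarray(group)
    if X_fixed is None or (hasattr(X_fixed, "size") and np.size(X_fixed) == 0):
        X = np.empty((y.size, 0))
    else:
        X = np.atleast_2d(np.asarray(X_fixed, dtype=float))
        if X.shape[0] != y.size:
            X = X.T
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    exog = np.column_stack([np.ones(n), X])
    fixed_names = ["intercept"] + list(names)
    k_par = p + 1 + 2  # fixed effects + group variance + residual variance

    if np.unique(group).size < 2:
        warnings.warn(
            "single group: random-intercept variance is not identifiable, reported as 0", stacklevel=2
        )
        return _ols_boundary_fit(y, exog, fixed_names, k_par)

    boundary = _ols_boundary_fit(y, exog, fixed_names, k_par)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, exog, groups=group)
            res = model.fit(reml=False, maxiter=500)
            llf = float(res.llf)
            bse = np.asarray(res.bse_fe, dtype=float)
            fe = np.asarray(res.fe_params, dtype=float)
            var_re = float(np.squeeze(res.cov_re))
            scale = float(res.scale)
    except Exception:
        return boundary
    # reject degenerate optimiser output and zero-boundary solutions that OLS beats
    if not np.isfinite(llf) or not np.all(np.isfinite(fe)) or llf < boundary.log_likelihood - 1e-8:
        return boundary
    return MixedFit(
        fixed_names=fixed_names,
        fixed_coefficients=fe,
        fixed_se=bse,
        random_intercept_var=var_re,
        residual_var=scale,
        aic=2 * k_par - 2 * llf,
        log_likelihood=llf,
        n=n,
    )
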
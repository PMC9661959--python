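"""Gaussian GLM, cubic-spline smooth fit and the ANOVA model choice between them."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.interpolate import BSpline

__all__ = ["GLMFit", "SmoothFit", "fit_glm_gaussian", "fit_smooth", "compare_models"]


@dataclass
class GLMFit:
    """Least-squares linear fit of y on x."""

    coefficients: np.ndarray  # (intercept, slope)
    deviance_explained: float
    df_residual: int
    residuals: np.ndarray
    fitted: np.ndarray
    rss: float

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slope(self) -> float:
        return float(self.coefficients[1])

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


@dataclass
class SmoothFit:
    """Cubic regression-spline fit of y on x."""

    coefficients: np.ndarray
    deviance_explained: float
    df_residual: int
    residuals: np.ndarray
    fitted: np.ndarray
    rss: float
    knots: np.ndarray
    degree: int = 3

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def predict(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.knots[self.degree], self.knots[-self.degree - 1])
        B = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        return B @ self.coefficients


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - fitted) ** 2))
    if tss == 0:
        return 1.0
    return max(0.0, min(1.0, 1.0 - rss / tss))


def fit_glm_gaussian(x, y) -> GLMFit:
    """Gaussian GLM (identity link): ordinary least squares of y on x."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("no variation in predictor")
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    return GLMFit(
        coefficients=coef,
        deviance_explained=_r2(y, fitted),
        df_residual=n - 2,
        residuals=resid,
        fitted=fitted,
        rss=rss,
    )


def fit_smooth(x, y, df: int = 4) -> SmoothFit:
    """Cubic regression spline with ``df`` basis functions (including intercept span).

    Interior knots are placed at quantiles of x; the fit is unpenalised
    least squares on the B-spline design matrix.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if df <= 1:
        raise ValueError("smooth df must exceed 1")
    if df >= n:
        raise ValueError("smooth df must be below the number of observations")
    degree = 3
    n_interior = max(df - degree - 1, 0)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("no variation in predictor")
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(x, knots, degree).toarray()
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    fitted = B @ coef
    resid = y - fitted
    return SmoothFit(
        coefficients=coef,
        deviance_explained=_r2(y, fitted),
        df_residual=n - B.shape[1],
        residuals=resid,
        fitted=fitted,
        rss=float(resid @ resid),
        knots=knots,
        degree=degree,
    )


def compare_models(glm_fit: GLMFit, smooth_fit: SmoothFit, alpha: float = 0.05):
    """F-test between the nested linear and smooth fits; keep the simpler model
    when they do not differ significantly.

    Returns ``(chosen_fit, label, p_value)`` where label is ``"glm"`` or ``"smooth"``.
    """
    d_df = smooth_fit.n_params - 2
    d_rss = glm_fit.rss - smooth_fit.rss
    if d_df <= 0 or d_rss <= 0 or smooth_fit.rss <= 0 or smooth_fit.df_residual <= 0:
        return glm_fit, "glm", 1.0
    f_stat = (d_rss / d_df) / (smooth_fit.rss / smooth_fit.df_residual)
    p = float(sps.f.sf(f_stat, d_df, smooth_fit.df_residual))
    if p < alpha:
        return smooth_fit, "smooth", p
    return glm_fit, "glm", p
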
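"""Moran's I spatial autocorrelation diagnostic for model residuals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

__all__ = ["morans_i", "MoranResult"]


@dataclass(frozen=True)
class MoranResult:
    I: float
    expected: float
    z: float
    p_value: float
    n: int


def _weights(coords: np.ndarray, kind: str) -> np.ndarray:
    n = coords.shape[0]
    if kind == "inverse_distance":
        d = cdist(coords, coords)
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
        if not np.all(np.isfinite(w[~np.eye(n, dtype=bool)])):
            raise ValueError("duplicate coordinates yield infinite inverse-distance weights")
    elif kind == "rook":
        d = cdist(coords, coords)
        off = d[~np.eye(n, dtype=bool)]
        step = off.min()
        w = ((d > 0) & (d <= step * 1.0001)).astype(float)
    else:
        raise ValueError("weights must be 'inverse_distance' or 'rook'")
    return w


def morans_i(
    values,
    coords,
    weights: str = "inverse_distance",
    row_standardize: bool = True,
) -> MoranResult:
    """Moran's I with a normal-approximation p-value.

    ``coords`` is an (n, 2) array of point locations.  ``weights`` selects
    inverse-distance weights (default) or rook contiguity (nearest grid step).
    """
    x = np.asarray(values, dtype=float).ravel()
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in values")
    w = _weights(coords, weights)
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs

    z = x - x.mean()
    s0 = w.sum()
    I = float(n / s0 * (z @ w @ z.T) / (z @ z))
    e_i = -1.0 / (n - 1)

    # variance under the normality assumption
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var = (n * n * s1 - n * s2 + 3 * s0 * s0) / (s0 * s0 * (n * n - 1)) - e_i**2
    var = max(var, 1e-300)
    z_score = (I - e_i) / np.sqrt(var)
    p = float(2 * sps.norm.sf(abs(z_score)))
    return MoranResult(I=I, expected=e_i, z=float(z_score), p_value=p, n=n)
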
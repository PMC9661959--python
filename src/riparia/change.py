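"""Baseline-vs-scenario comparison: delta rasters, high-risk change masks,
random point sampling and multi-scale change aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grids import RasterGrid, require_same_grid
from .synthetic import CapacityError

__all__ = [
    "CHANGE_CODES",
    "delta_raster",
    "high_risk_change_mask",
    "sample_random_points",
    "aggregate_change",
    "habitat_summary",
]

CHANGE_CODES = {"stable_low": 0, "new_high": 1, "lost_high": 2, "stable_high": 3}


def delta_raster(baseline: RasterGrid, scenario: RasterGrid) -> RasterGrid:
    """Pixelwise scenario - baseline; nodata (NaN) propagates."""
    require_same_grid(baseline, scenario)
    return baseline.like(scenario.values.astype(float) - baseline.values.astype(float), name="delta")


def high_risk_change_mask(baseline: RasterGrid, scenario: RasterGrid, threshold: float = 0.5) -> RasterGrid:
    """Categorise pixels by whether risk crosses the (strict) threshold.

    Categories: stable_low, new_high (crossed up), lost_high (crossed down),
    stable_high.  NaN in either input yields -1 (nodata).
    """
    require_same_grid(baseline, scenario)
    b = baseline.values.astype(float)
    s = scenario.values.astype(float)
    hi_b = b > threshold
    hi_s = s > threshold
    out = np.full(b.shape, CHANGE_CODES["stable_low"], dtype=np.int16)
    out[hi_s & ~hi_b] = CHANGE_CODES["new_high"]
    out[~hi_s & hi_b] = CHANGE_CODES["lost_high"]
    out[hi_s & hi_b] = CHANGE_CODES["stable_high"]
    out[np.isnan(b) | np.isnan(s)] = -1
    grid = baseline.like(out, name="high_risk_change")
    grid.nodata_value = -1
    return grid


def sample_random_points(mask: RasterGrid, n: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """n distinct pixel centres drawn uniformly (without replacement) from a
    boolean mask raster; returns (x, y) arrays."""
    m = mask.values.astype(bool)
    rows, cols = np.where(m)
    if rows.size < n:
        raise CapacityError(f"mask has {rows.size} pixels but {n} points requested")
    rng = np.random.default_rng(seed)
    k = rng.choice(rows.size, size=n, replace=False)
    return mask.spec.cell_center(rows[k], cols[k])


def aggregate_change(
    metrics: dict[str, tuple[RasterGrid, RasterGrid]],
    units: pd.DataFrame,
) -> pd.DataFrame:
    """Per-unit change table for each metric.

    ``metrics`` maps metric_id -> (baseline raster, scenario raster).
    ``units`` has columns unit ('plot' | 'habitat' | 'production_system'),
    unit_id, x, y; a unit may own many points and its value is the mean over
    them.  Units whose points all fall on nodata get NaN rows (reported, not
    dropped).
    """
    required = {"unit", "unit_id", "x", "y"}
    if not required <= set(units.columns):
        raise ValueError(f"units table needs columns {sorted(required)}")
    rows = []
    for metric_id, (base, scen) in metrics.items():
        require_same_grid(base, scen)
        bvals = base.sample(units["x"].to_numpy(), units["y"].to_numpy()).astype(float)
        svals = scen.sample(units["x"].to_numpy(), units["y"].to_numpy()).astype(float)
        tmp = units.assign(_b=bvals, _s=svals)
        for (unit, unit_id), sub in tmp.groupby(["unit", "unit_id"], sort=False):
            b = float(np.nanmean(sub["_b"])) if sub["_b"].notna().any() else np.nan
            s = float(np.nanmean(sub["_s"])) if sub["_s"].notna().any() else np.nan
            rows.append(
                {
                    "metric_id": metric_id,
                    "unit": unit,
                    "unit_id": unit_id,
                    "baseline_value": b,
                    "scenario_value": s,
                    "delta": s - b,
                    "n_points": len(sub),
                }
            )
    return pd.DataFrame(rows)


def habitat_summary(plots: pd.DataFrame, value_col: str, habitat_col: str = "habitat") -> dict:
    """Per-habitat mean +/- sd with one-way ANOVA and Tukey HSD pairwise tests.

    With a single habitat the summary is returned and the tests are skipped
    (``note`` explains why).  Tukey uses the Tukey-Kramer adjustment for
    unequal group sizes.
    """
    df = plots.dropna(subset=[value_col])
    groups = {h: sub[value_col].to_numpy(dtype=float) for h, sub in df.groupby(habitat_col)}
    summary = pd.DataFrame(
        {
            "habitat": list(groups),
            "n": [g.size for g in groups.values()],
            "mean": [g.mean() for g in groups.values()],
            "sd": [g.std(ddof=1) if g.size > 1 else np.nan for g in groups.values()],
        }
    )
    testable = {h: g for h, g in groups.items() if g.size >= 2}
    if len(testable) < 2:
        return {"summary": summary, "anova": None, "tukey": None, "note": "fewer than two habitats with >=2 plots; tests skipped"}
    names = list(testable)
    f_stat, p = sps.f_oneway(*testable.values())
    tk = sps.tukey_hsd(*testable.values())
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairs.append(
                {
                    "habitat_a": names[i],
                    "habitat_b": names[j],
                    "mean_diff": testable[names[i]].mean() - testable[names[j]].mean(),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
    return {
        "summary": summary,
        "anova": {"F": float(f_stat), "p": float(p)},
        "tukey": pd.DataFrame(pairs),
        "note": None,
    }
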
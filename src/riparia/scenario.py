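"""Riparian-buffer restoration scenario: landcover edit and stack rebuild.

The scenario converts every convertible pixel (not water, not settlement)
whose centre lies within a half-width of a river centreline to forest, then
imputes canopy attributes for the new forest from the current-forest
distribution and recomputes the forest-derived covariate layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .covariates import (
    LANDCOVER_CODES,
    CovariateStack,
    distance_to_class,
    distance_to_lines,
    focal_stats,
    percent_class_in_window,
)
from .grids import RasterGrid

__all__ = [
    "ScenarioConfig",
    "apply_riparian_buffer",
    "impute_restored_attributes",
    "rebuild_scenario_stack",
    "NoDonorError",
]

# landcover classes that are never planted over
_UNCONVERTIBLE = (LANDCOVER_CODES["water"], LANDCOVER_CODES["settlement"])


class NoDonorError(ValueError):
    """No current forest pixels to borrow attribute values from."""


@dataclass(frozen=True)
class ScenarioConfig:
    buffer_half_width: float = 60.0  # metres on each side of the river line
    attribute_imputation: str = "mean"  # "mean" | "sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer_half_width <= 0:
            raise ValueError("buffer half-width must be positive")
        if self.attribute_imputation not in ("mean", "sample"):
            raise ValueError("attribute_imputation must be 'mean' or 'sample'")


def apply_riparian_buffer(landcover: RasterGrid, rivers, config: ScenarioConfig | None = None) -> RasterGrid:
    """Convert convertible pixels within the buffer of river lines to forest.

    Distance is measured from pixel centres to the river centreline
    polylines; water and settlement pixels are never converted.  With an
    empty river set the input is returned unchanged (with a warning).
    """
    config = config or ScenarioConfig()
    rivers = list(rivers)
    if not rivers:
        warnings.warn("empty river set: scenario leaves the landcover unchanged", stacklevel=2)
        return landcover.like(landcover.values.copy(), name="landcover_scenario")
    dist = distance_to_lines(landcover.spec, rivers).values
    convertible = ~np.isin(landcover.values, _UNCONVERTIBLE)
    new_lc = landcover.values.copy()
    new_lc[(dist <= config.buffer_half_width) & convertible] = LANDCOVER_CODES["forest"]
    return landcover.like(new_lc, name="landcover_scenario")


def impute_restored_attributes(
    layer: RasterGrid,
    new_forest: np.ndarray,
    donor_values: np.ndarray,
    config: ScenarioConfig | None = None,
) -> RasterGrid:
    """Fill an attribute layer on new-forest pixels from the current-forest
    empirical distribution (donor mean, or seeded draws from the donors)."""
    config = config or ScenarioConfig()
    donor_values = np.asarray(donor_values, dtype=float).ravel()
    donor_values = donor_values[~np.isnan(donor_values)]
    if donor_values.size == 0:
        raise NoDonorError("no current forest pixels provide a donor distribution")
    new_forest = np.asarray(new_forest, dtype=bool)
    out = layer.values.astype(float).copy()
    k = int(new_forest.sum())
    if k:
        if config.attribute_imputation == "mean":
            out[new_forest] = donor_values.mean()
        else:
            rng = np.random.default_rng(config.seed)
            out[new_forest] = rng.choice(donor_values, size=k, replace=True)
    return layer.like(out)


def rebuild_scenario_stack(
    bundle,
    baseline_stack: CovariateStack,
    scenario_landcover: RasterGrid,
    config: ScenarioConfig | None = None,
) -> CovariateStack:
    """Recompute the forest- and canopy-derived layers under the scenario.

    Updated: dist_forest, pct_forest_250, canopy closure and NDVI (imputed
    on new forest) and all their focal layers.  Everything else (river/road/
    settlement/plantation distances, population, canopy height) is copied
    from the baseline.
    """
    config = config or ScenarioConfig()
    forest_code = LANDCOVER_CODES["forest"]
    baseline_forest = bundle.landcover.values == forest_code
    new_forest = (scenario_landcover.values == forest_code) & ~baseline_forest

    stack = baseline_stack.copy(provenance="scenario")
    layers = stack.layers

    cc = baseline_stack["canopy_closure"]
    ndvi = baseline_stack["ndvi"]
    if new_forest.any():
        cc_donors = cc.values[baseline_forest]
        ndvi_donors = ndvi.values[baseline_forest]
        cc = impute_restored_attributes(cc, new_forest, cc_donors, config)
        ndvi = impute_restored_attributes(ndvi, new_forest, ndvi_donors, config)

    layers["canopy_closure"] = cc
    layers["ndvi"] = ndvi
    layers["dist_forest"] = distance_to_class(scenario_landcover, "forest")
    layers["pct_forest_250"] = percent_class_in_window(scenario_landcover, "forest", 250.0)
    for radius in (150.0, 500.0):
        r = int(radius)
        layers[f"ndvi_mean_{r}"] = focal_stats(ndvi, radius, "mean")
        layers[f"ndvi_sd_{r}"] = focal_stats(ndvi, radius, "sd")
        layers[f"canopy_closure_mean_{r}"] = focal_stats(cc, radius, "mean")
        layers[f"canopy_closure_sd_{r}"] = focal_stats(cc, radius, "sd")
    return stack
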
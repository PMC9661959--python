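"""Derivation of the predictor raster stack from a landscape bundle.

Layers: canopy closure, Euclidean distances to forest / river / road /
settlement / plantation, NDVI, percent forest in a 250 m window, focal mean
and standard deviation of NDVI and canopy closure in 150 m and 500 m
windows, population density, and canopy height.

Windows are circular on pixel centres with the focal pixel included; edge
windows use the available in-extent pixels only.  Distances are exact
pixel-centre Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .grids import GridSpec, RasterGrid, require_same_grid

__all__ = [
    "CovariateStack",
    "EmptyTargetError",
    "distance_to_class",
    "distance_to_lines",
    "focal_stats",
    "percent_class_in_window",
    "correlation_filter",
    "build_stack",
    "extract_at_points",
    "STACK_LAYER_NAMES",
]

log = logging.getLogger(__name__)

# landcover class codes used throughout the package
LANDCOVER_CODES = {"forest": 1, "grassland": 2, "cropland": 3, "water": 4, "settlement": 5}

STACK_LAYER_NAMES = [
    "canopy_closure",
    "dist_forest",
    "dist_river",
    "dist_road",
    "dist_settlement",
    "dist_plantation",
    "ndvi",
    "pct_forest_250",
    "ndvi_mean_150",
    "ndvi_sd_150",
    "ndvi_mean_500",
    "ndvi_sd_500",
    "canopy_closure_mean_150",
    "canopy_closure_sd_150",
    "canopy_closure_mean_500",
    "canopy_closure_sd_500",
    "pop_density",
    "canopy_height",
]


class EmptyTargetError(ValueError):
    """Distance target contains no pixels/features."""


@dataclass
class CovariateStack:
    """Named predictor raster layers sharing one grid."""

    spec: GridSpec
    layers: dict[str, RasterGrid]
    provenance: str = "baseline"

    def __post_init__(self) -> None:
        for name, layer in self.layers.items():
            if layer.spec != self.spec:
                raise ValueError(f"layer {name!r} is not on the stack grid")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def copy(self, provenance: str | None = None) -> "CovariateStack":
        return CovariateStack(
            self.spec,
            {k: RasterGrid(v.spec, v.values.copy(), v.nodata_value, v.name) for k, v in self.layers.items()},
            provenance or self.provenance,
        )

    def as_table(self) -> dict[str, np.ndarray]:
        return {k: v.values for k, v in self.layers.items()}


def distance_to_class(landcover: RasterGrid, target) -> RasterGrid:
    """Euclidean distance (metres, pixel centres) to the nearest target pixel.

    ``target`` is a class name/code or a boolean mask raster/array.
    """
    if isinstance(target, RasterGrid):
        mask = target.values.astype(bool)
    elif isinstance(target, np.ndarray):
        mask = target.astype(bool)
    else:
        code = LANDCOVER_CODES.get(target, target)
        mask = landcover.values == code
    if not mask.any():
        raise EmptyTargetError(f"no target pixels for {target!r}")
    res = landcover.spec.resolution
    dist = ndimage.distance_transform_edt(~mask, sampling=res)
    return landcover.like(dist.astype(float), name="distance")


def distance_to_lines(spec: GridSpec, lines: Iterable[shapely.Geometry]) -> RasterGrid:
    """Distance from every pixel centre to the nearest polyline (metres)."""
    geoms = list(lines)
    if not geoms:
        raise EmptyTargetError("empty polyline set")
    merged = shapely.union_all(geoms)
    xs, ys = spec.cell_centers()
    pts = shapely.points(np.column_stack([xs.ravel(), ys.ravel()]))
    d = shapely.distance(pts, merged).reshape(spec.shape)
    return RasterGrid(spec, d, name="distance")


def _circular_footprint(radius_m: float, resolution: float) -> np.ndarray:
    r_px = int(np.floor(radius_m / resolution))
    dr, dc = np.mgrid[-r_px : r_px + 1, -r_px : r_px + 1]
    return (dr * dr + dc * dc) * resolution**2 <= radius_m**2 + 1e-9


def focal_stats(layer: RasterGrid, radius: float, stat: str = "mean") -> RasterGrid:
    """Circular-window focal mean or population standard deviation.

    The window covers all pixels whose centres lie within ``radius`` metres
    of the focal pixel centre (focal pixel included).  Nodata pixels are
    excluded; edge windows shrink to the in-extent pixels.
    """
    res = layer.spec.resolution
    if radius < res:
        raise ValueError("radius must be at least one pixel")
    if stat not in ("mean", "sd"):
        raise ValueError("stat must be 'mean' or 'sd'")
    fp = _circular_footprint(radius, res).astype(float)
    valid = layer.valid_mask
    vals = np.where(valid, layer.values.astype(float), 0.0)

    counts = ndimage.convolve(valid.astype(float), fp, mode="constant", cval=0.0)
    sums = ndimage.convolve(vals, fp, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    if stat == "mean":
        out = mean
    else:
        sq = ndimage.convolve(vals * vals, fp, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = sq / counts - mean * mean
        out = np.sqrt(np.clip(var, 0.0, None))
    out[counts == 0] = np.nan
    return layer.like(out, name=f"{layer.name}_{stat}_{int(radius)}")


def percent_class_in_window(landcover: RasterGrid, target, radius: float = 250.0) -> RasterGrid:
    """Percent of valid window pixels belonging to the target class, in [0, 100]."""
    code = LANDCOVER_CODES.get(target, target)
    indicator = landcover.like((landcover.values == code).astype(float) * 100.0)
    indicator.nodata_value = None
    # carry over nodata from the landcover raster
    vals = indicator.values.copy()
    vals[~landcover.valid_mask] = np.nan
    return focal_stats(landcover.like(vals), radius, "mean")


def correlation_filter(
    samples: pd.DataFrame | Mapping[str, np.ndarray],
    threshold: float = 0.7,
    order: Sequence[str] | None = None,
) -> list[str]:
    """Greedy Pearson-correlation screen over covariate columns.

    Scans covariates in declared order; a covariate is dropped when its
    absolute correlation with any already-retained covariate reaches the
    threshold.  Zero-variance covariates are dropped with a warning.
    """
    df = pd.DataFrame(samples)
    if order is None:
        order = list(df.columns)
    if len(df) < 3:
        raise ValueError("need at least 3 sample points")
    retained: list[str] = []
    for name in order:
        col = df[name].to_numpy(dtype=float)
        if np.nanstd(col) == 0:
            warnings.warn(f"covariate {name!r} has zero variance; dropped", stacklevel=2)
            continue
        ok = True
        for kept in retained:
            r = np.corrcoef(col, df[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) >= threshold:
                log.info("correlation filter: dropping %s (|r|=%.3f with %s)", name, abs(r), kept)
                ok = False
                break
        if ok:
            retained.append(name)
    return retained


def build_stack(bundle) -> CovariateStack:
    """Assemble the full baseline covariate stack from a landscape bundle."""
    lc = bundle.landcover
    spec = lc.spec
    layers: dict[str, RasterGrid] = {}
    layers["canopy_closure"] = bundle.canopy_closure

    try:
        layers["dist_forest"] = distance_to_class(lc, "forest")
    except EmptyTargetError as e:
        raise EmptyTargetError(f"dist_forest: {e}") from e
    for name, geoms in (("dist_river", bundle.rivers), ("dist_road", bundle.roads)):
        try:
            layers[name] = distance_to_lines(spec, geoms)
        except EmptyTargetError as e:
            raise EmptyTargetError(f"{name}: {e}") from e
    try:
        layers["dist_settlement"] = distance_to_class(lc, "settlement")
    except EmptyTargetError as e:
        raise EmptyTargetError(f"dist_settlement: {e}") from e
    try:
        layers["dist_plantation"] = distance_to_class(lc, bundle.plantation_mask.values.astype(bool))
    except EmptyTargetError as e:
        raise EmptyTargetError(f"dist_plantation: {e}") from e

    layers["ndvi"] = bundle.ndvi
    layers["pct_forest_250"] = percent_class_in_window(lc, "forest", 250.0)
    for radius in (150.0, 500.0):
        r = int(radius)
        layers[f"ndvi_mean_{r}"] = focal_stats(bundle.ndvi, radius, "mean")
        layers[f"ndvi_sd_{r}"] = focal_stats(bundle.ndvi, radius, "sd")
        layers[f"canopy_closure_mean_{r}"] = focal_stats(bundle.canopy_closure, radius, "mean")
        layers[f"canopy_closure_sd_{r}"] = focal_stats(bundle.canopy_closure, radius, "sd")
    layers["pop_density"] = bundle.pop_density
    layers["canopy_height"] = bundle.canopy_height
    return CovariateStack(spec, {k: layers[k] for k in STACK_LAYER_NAMES}, provenance="baseline")


def extract_at_points(stack: CovariateStack, x, y, point_ids=None) -> pd.DataFrame:
    """Sample every stack layer at world points; one row per point."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if point_ids is None:
        point_ids = np.arange(x.size)
    data = {"point_id": point_ids, "x": x, "y": y}
    for name, layer in stack.layers.items():
        data[name] = layer.sample(x, y)
    return pd.DataFrame(data)
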
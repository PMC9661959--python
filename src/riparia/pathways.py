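"""The three framework pathways: response construction and model wiring.

Pathway 1 relates plot microclimate/yield to canopy closure (GLM vs smooth,
ANOVA choice).  Pathway 2 classifies locations into richness/presence
classes and fits covariate-selected discriminant models, mapped to per-class
probability rasters.  Pathway 3 does the same for crop-raiding
presence/absence, producing a risk raster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CovariateStack, correlation_filter
from .grids import RasterGrid
from .stats import (
    ForwardStep,
    LDAModel,
    MoranResult,
    fit_glm_gaussian,
    fit_lda,
    fit_smooth,
    compare_models,
    greedy_wilks_forward,
    morans_i,
    predict_lda,
)

log = logging.getLogger(__name__)

__all__ = [
    "ConflictDataset",
    "classify_guild",
    "flag_threatened",
    "richness_classes",
    "fit_pathway1",
    "fit_pathway2",
    "fit_pathway3",
    "map_predictions",
    "Pathway1Fit",
    "PathwayLDAFit",
]

THREAT_CODES = {"LC", "NT", "VU", "EN", "CR", "DD"}
GUILD_ITEMS = ("invertebrate", "vertebrate", "plant_seed")


@dataclass
class ConflictDataset:
    """Presence/absence crop-raiding points with coordinates."""

    frame: pd.DataFrame  # columns: x, y, outcome (0/1)

    def __post_init__(self) -> None:
        missing = {"x", "y", "outcome"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"conflict dataset missing columns: {sorted(missing)}")
        if not set(np.unique(self.frame["outcome"])) <= {0, 1}:
            raise ValueError("conflict outcomes must be binary 0/1")

    @property
    def n_presence(self) -> int:
        return int((self.frame["outcome"] == 1).sum())

    @property
    def n_absence(self) -> int:
        return int((self.frame["outcome"] == 0).sum())


def classify_guild(trait) -> str:
    """Diet guild by the dominant (>50%) diet item; 'none' without one."""
    fracs = trait.diet_fractions
    total = sum(fracs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"diet fractions sum to {total}, not 1")
    for item in GUILD_ITEMS:
        if fracs.get(item, 0.0) > 0.5:
            return item
    return "none"


def flag_threatened(status: str) -> bool:
    """True iff the IUCN-style status is VU, EN or CR."""
    if status not in THREAT_CODES:
        raise ValueError(f"unknown threat status code: {status!r}")
    return status in ("VU", "EN", "CR")


def richness_classes(counts, n_classes: int = 3):
    """Quantile split of species counts into low/(medium/)high classes.

    Returns ``(labels, thresholds)``; thresholds are the training quantiles
    and can be reused on new counts.  Ties go to the lower class.
    """
    counts = np.asarray(counts, dtype=float)
    if n_classes not in (2, 3):
        raise ValueError("n_classes must be 2 or 3")
    if np.unique(counts).size < n_classes:
        raise ValueError("degenerate counts: fewer distinct values than classes")
    qs = [0.5] if n_classes == 2 else [1 / 3, 2 / 3]
    thresholds = np.quantile(counts, qs)
    names = ["low", "high"] if n_classes == 2 else ["low", "medium", "high"]
    idx = np.sum(counts[:, None] > thresholds[None, :], axis=1)
    labels = np.array([names[i] for i in idx])
    if np.unique(labels).size < n_classes:
        raise ValueError("degenerate counts: a quantile class is empty")
    return labels, thresholds


# ---------------------------------------------------------------------------
# pathway 1


@dataclass
class Pathway1Fit:
    response: str
    fit: object
    model_type: str  # "glm" | "smooth"
    anova_p: float
    n: int
    crop_type: str | None = None


def _fit_one_response(x, y, response, smooth_df=4, alpha=0.05, crop_type=None) -> Pathway1Fit:
    glm = fit_glm_gaussian(x, y)
    try:
        smooth = fit_smooth(x, y, df=smooth_df)
        chosen, label, p = compare_models(glm, smooth, alpha=alpha)
    except ValueError:
        chosen, label, p = glm, "glm", 1.0
    return Pathway1Fit(response=response, fit=chosen, model_type=label, anova_p=p, n=len(np.asarray(x)), crop_type=crop_type)


def fit_pathway1(plots: pd.DataFrame, min_plots: int = 10, smooth_df: int = 4, alpha: float = 0.05) -> dict:
    """Fit microclimate and yield responses against canopy closure.

    Responses: t_ground, t_leaf, fluorescence across all plots; yield per
    crop type on cropland plots.  Each response gets a GLM and a smooth fit
    with the ANOVA choice between them; crop types with too few plots are
    skipped with a log entry.
    """
    for col in ("canopy_closure", "t_ground", "t_leaf", "fluorescence"):
        if col not in plots.columns:
            raise KeyError(f"plot table is missing required column {col!r}")
    if len(plots) < min_plots:
        raise ValueError(f"need at least {min_plots} plots")
    fits: dict[str, Pathway1Fit] = {}
    cc = plots["canopy_closure"].to_numpy(dtype=float)
    for response in ("t_ground", "t_leaf", "fluorescence"):
        y = plots[response].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        fits[response] = _fit_one_response(cc[ok], y[ok], response, smooth_df, alpha)
    if "yield" in plots.columns and "crop_type" in plots.columns:
        for crop, sub in plots.dropna(subset=["yield"]).groupby("crop_type"):
            if len(sub) < 3:
                log.info("pathway 1: crop type %r has %d plots; skipped", crop, len(sub))
                continue
            fits[f"yield_{crop}"] = _fit_one_response(
                sub["canopy_closure"].to_numpy(float),
                sub["yield"].to_numpy(float),
                "yield",
                smooth_df,
                alpha,
                crop_type=crop,
            )
    return fits


# ---------------------------------------------------------------------------
# pathways 2 and 3 (LDA pipeline)


@dataclass
class PathwayLDAFit:
    metric_id: str
    model: LDAModel
    steps: list[ForwardStep]
    retained_covariates: list[str]
    moran: MoranResult | None
    n: int
    diagnostics: dict = field(default_factory=dict)


def _lda_pipeline(
    metric_id: str,
    labels: np.ndarray,
    covars: pd.DataFrame,
    coords: np.ndarray | None,
    p_enter: float,
    corr_threshold: float = 0.7,
) -> PathwayLDAFit:
    retained = correlation_filter(covars, threshold=corr_threshold)
    if not retained:
        raise ValueError(f"{metric_id}: no covariates survive the correlation filter")
    X = covars[retained].to_numpy(dtype=float)
    steps = greedy_wilks_forward(X, labels, p_enter=p_enter, names=retained)
    selected = [s.covariate for s in steps] or retained[:1]  # fall back to best single covariate
    if not steps:
        log.warning("%s: no covariate passed the entry test; using %r", metric_id, selected[0])
    model = fit_lda(covars[selected].to_numpy(dtype=float), labels, names=selected)

    moran = None
    if coords is not None:
        post = predict_lda(model, covars[selected].to_numpy(dtype=float))
        order = {c: i for i, c in enumerate(model.class_labels)}
        obs_rank = np.array([order[c] for c in labels], dtype=float)
        exp_rank = post @ np.arange(len(model.class_labels))
        resid = obs_rank - exp_rank
        try:
            moran = morans_i(resid, coords)
        except ValueError:
            moran = None
    return PathwayLDAFit(
        metric_id=metric_id,
        model=model,
        steps=steps,
        retained_covariates=retained,
        moran=moran,
        n=len(labels),
        diagnostics={"wilks_path": [s.wilks for s in steps]},
    )


def fit_pathway2(
    responses: pd.DataFrame,
    stack_at_points: pd.DataFrame,
    p_enter: float = 0.05,
    covariate_names: list[str] | None = None,
) -> dict:
    """Fit one covariate-selected LDA per biodiversity metric.

    ``responses`` has columns (metric_id, location_id, label); covariates
    are joined on location_id.  Metrics with a single observed class are
    skipped and reported under the ``"skipped"`` key.
    """
    if covariate_names is None:
        covariate_names = [
            c for c in stack_at_points.columns if c not in ("location_id", "point_id", "x", "y")
        ]
    out: dict[str, PathwayLDAFit] = {}
    skipped: dict[str, str] = {}
    for metric_id, sub in responses.groupby("metric_id"):
        merged = sub.merge(stack_at_points, on="location_id", how="inner")
        labels = merged["label"].to_numpy()
        if np.unique(labels).size < 2:
            skipped[metric_id] = "single observed class"
            log.warning("pathway 2: metric %s skipped (single observed class)", metric_id)
            continue
        coords = merged[["x", "y"]].to_numpy(dtype=float) if {"x", "y"} <= set(merged.columns) else None
        out[metric_id] = _lda_pipeline(metric_id, labels, merged[covariate_names], coords, p_enter)
    out["skipped"] = skipped  # type: ignore[assignment]
    return out


def map_predictions(model: LDAModel, stack: CovariateStack) -> dict[str, RasterGrid]:
    """Per-class posterior probability rasters; pixel probabilities sum to 1."""
    missing = [c for c in model.covariate_names if c not in stack]
    if missing:
        raise KeyError(f"stack is missing model covariates: {missing}")
    spec = stack.spec
    X = np.column_stack([stack[c].values.ravel() for c in model.covariate_names]).astype(float)
    valid = ~np.isnan(X).any(axis=1)
    post = np.full((X.shape[0], len(model.class_labels)), np.nan)
    if valid.any():
        post[valid] = predict_lda(model, X[valid])
    return {
        str(cls): RasterGrid(spec, post[:, i].reshape(spec.shape), name=f"p_{cls}")
        for i, cls in enumerate(model.class_labels)
    }


def fit_pathway3(
    conflict: ConflictDataset,
    stack_at_points: pd.DataFrame,
    p_enter: float = 0.05,
    covariate_names: list[str] | None = None,
) -> PathwayLDAFit:
    """Covariate-selected LDA for crop-raiding presence/absence."""
    if conflict.n_presence == 0 or conflict.n_absence == 0:
        raise ValueError("conflict dataset must contain both presence and absence points")
    if covariate_names is None:
        covariate_names = [
            c for c in stack_at_points.columns if c not in ("location_id", "point_id", "x", "y")
        ]
    labels = np.where(conflict.frame["outcome"].to_numpy() == 1, "presence", "absence")
    coords = conflict.frame[["x", "y"]].to_numpy(dtype=float)
    return _lda_pipeline("crop_raiding", labels, stack_at_points[covariate_names], coords, p_enter)


def predict_risk(fit: PathwayLDAFit, stack: CovariateStack) -> RasterGrid:
    """Presence-posterior raster for a pathway-3 fit, values in [0, 1]."""
    rasters = map_predictions(fit.model, stack)
    return rasters["presence"]
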
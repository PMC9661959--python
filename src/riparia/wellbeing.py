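"""Composite wellbeing index and social-pathway models.

Twenty survey indicators map onto five dimensions (basic material, health,
social relations, security, freedom of choice and action).  Indicators are
normalised to [0, 1] on their declared ranges (reversed for lower-is-better
items); each dimension score is the mean of its indicators and the index is
the mean of the five dimension scores, so every dimension carries equal
weight regardless of its indicator count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MixedFit, OrdinalFit, fit_proportional_odds, fit_random_intercept_lm

__all__ = [
    "Indicator",
    "IndicatorSchema",
    "default_schema",
    "normalize_indicators",
    "composite_index",
    "damage_effects_model",
    "perception_model",
]

DIMENSIONS = ("basic_material", "health", "social_relations", "security", "freedom_choice")


@dataclass(frozen=True)
class Indicator:
    name: str
    dimension: str
    min: float
    max: float
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not self.min < self.max:
            raise ValueError(f"indicator {self.name!r}: min must be below max")


@dataclass(frozen=True)
class IndicatorSchema:
    indicators: tuple

    def __post_init__(self) -> None:
        if len(self.indicators) != 20:
            raise ValueError(f"schema must define exactly 20 indicators, got {len(self.indicators)}")
        dims = {d: 0 for d in DIMENSIONS}
        for ind in self.indicators:
            dims[ind.dimension] += 1
        empty = [d for d, k in dims.items() if k == 0]
        if empty:
            raise ValueError(f"dimensions without indicators: {empty}")

    @property
    def names(self) -> list[str]:
        return [i.name for i in self.indicators]

    def by_dimension(self) -> dict:
        out: dict[str, list[Indicator]] = {d: [] for d in DIMENSIONS}
        for ind in self.indicators:
            out[ind.dimension].append(ind)
        return out


def default_schema() -> IndicatorSchema:
    """The shipped 20-indicator schema with plausible declared ranges."""
    spec = [
        # basic material for a good life
        ("financial_savings", "basic_material", 0, 5, True),
        ("wall_material", "basic_material", 0, 4, True),
        ("household_assets", "basic_material", 0, 10, True),
        ("banking", "basic_material", 0, 1, True),
        ("water_access", "basic_material", 0, 4, True),
        ("land_ownership", "basic_material", 0, 10, True),
        ("livestock", "basic_material", 0, 20, True),
        # health
        ("sickness", "health", 0, 5, False),
        ("health_insurance", "health", 0, 1, True),
        ("diet", "health", 0, 7, True),
        # social relations
        ("borrowing", "social_relations", 0, 5, False),
        ("recognition", "social_relations", 0, 4, True),
        ("provision_dependents", "social_relations", 0, 4, True),
        ("provision_old_age", "social_relations", 0, 4, True),
        # security
        ("theft_security", "security", 0, 4, True),
        ("n_livelihoods", "security", 0, 6, True),
        # freedom of choice and action
        ("livelihood_satisfaction", "freedom_choice", 0, 4, True),
        ("nature_access", "freedom_choice", 0, 4, True),
        ("education", "freedom_choice", 0, 7, True),
        ("quality_of_life", "freedom_choice", 0, 4, True),
    ]
    return IndicatorSchema(tuple(Indicator(n, d, float(lo), float(hi), hib) for n, d, lo, hi, hib in spec))


def normalize_indicators(records: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Map raw indicator columns to [0, 1] on their declared ranges.

    Lower-is-better indicators are reversed so 1 is always the good end.
    Out-of-range values raise, naming household and indicator.
    """
    out = pd.DataFrame(index=records.index)
    ids = records["household_id"] if "household_id" in records.columns else records.index
    for ind in schema.indicators:
        if ind.name not in records.columns:
            raise KeyError(f"missing indicator column {ind.name!r}")
        x = records[ind.name].to_numpy(dtype=float)
        bad = (x < ind.min) | (x > ind.max)
        if bad.any():
            hh = np.asarray(ids)[bad][0]
            hh = hh.item() if hasattr(hh, "item") else hh
            raise ValueError(
                f"indicator {ind.name!r} out of declared range [{ind.min}, {ind.max}] "
                f"for household {hh!r}"
            )
        norm = (x - ind.min) / (ind.max - ind.min)
        out[ind.name] = norm if ind.higher_is_better else 1.0 - norm
    return out


def composite_index(normalized: pd.DataFrame, schema: IndicatorSchema) -> pd.DataFrame:
    """Dimension scores and the equal-dimension-weight composite index."""
    missing = [i.name for i in schema.indicators if i.name not in normalized.columns]
    if missing:
        raise KeyError(f"missing normalized indicators: {missing}")
    out = pd.DataFrame(index=normalized.index)
    for dim, inds in schema.by_dimension().items():
        out[dim] = normalized[[i.name for i in inds]].mean(axis=1)
    out["index"] = out[list(DIMENSIONS)].mean(axis=1)
    return out


def _gender_numeric(g: pd.Series) -> np.ndarray:
    return (g.astype(str) == "woman").to_numpy(dtype=float)


def damage_effects_model(
    index: pd.Series | np.ndarray,
    damage_wildlife,
    damage_elephant,
    gender,
    village,
) -> dict:
    """Nested random-intercept models of wellbeing: null, +damage, +gender.

    Returns the fitted models keyed by name plus an AIC comparison table
    under ``"comparison"``.
    """
    y = np.asarray(index, dtype=float)
    village = np.asarray(village)
    if np.unique(village).size < 2:
        raise ValueError("need at least two villages for the random intercept")
    woman = _gender_numeric(pd.Series(gender))
    dmg_w = np.asarray(damage_wildlife, dtype=float)
    dmg_e = np.asarray(damage_elephant, dtype=float)

    fits: dict[str, MixedFit] = {
        "null": fit_random_intercept_lm(y, None, village, names=[]),
        "damage_wildlife": fit_random_intercept_lm(y, dmg_w[:, None], village, names=["crop_damage_wildlife"]),
        "damage_elephant": fit_random_intercept_lm(y, dmg_e[:, None], village, names=["crop_damage_elephant"]),
        "gender": fit_random_intercept_lm(y, woman[:, None], village, names=["woman"]),
    }
    comparison = pd.DataFrame(
        {"model": list(fits), "aic": [f.aic for f in fits.values()], "log_likelihood": [f.log_likelihood for f in fits.values()]}
    ).sort_values("aic", ignore_index=True)
    return {**fits, "comparison": comparison}


def perception_model(
    perception,
    index,
    gender,
    village,
    damage_wildlife,
    damage_elephant,
    include_village: bool = True,
) -> dict:
    """Proportional-odds models of nature perception (ordinal 0-4).

    Fits baseline (village only), +wellbeing, +wellbeing+gender and
    +wellbeing+gender+damage models and returns them with an AIC table.
    """
    y = np.asarray(perception, dtype=int)
    if y.min() < 0 or y.max() > 4:
        raise ValueError("perception must be coded 0-4")
    w = np.asarray(index, dtype=float)
    woman = _gender_numeric(pd.Series(gender))
    village = pd.Series(np.asarray(village))
    dmg_w = np.asarray(damage_wildlife, dtype=float)
    dmg_e = np.asarray(damage_elephant, dtype=float)

    if include_village and village.nunique() > 1:
        vd = pd.get_dummies(village, prefix="village", drop_first=True).to_numpy(dtype=float)
        v_names = list(pd.get_dummies(village, prefix="village", drop_first=True).columns)
    else:
        vd = np.empty((len(y), 0))
        v_names = []

    def fit(cols, names):
        X = np.column_stack(cols + [vd]) if cols else (vd if vd.size else np.empty((len(y), 0)))
        return fit_proportional_odds(y, X, names=names + v_names)

    fits: dict[str, OrdinalFit] = {
        "baseline": fit([], []),
        "wellbeing": fit([w[:, None]], ["wellbeing"]),
        "wellbeing_gender": fit([w[:, None], woman[:, None]], ["wellbeing", "woman"]),
        "wellbeing_gender_damage": fit(
            [w[:, None], woman[:, None], dmg_w[:, None], dmg_e[:, None]],
            ["wellbeing", "woman", "crop_damage_wildlife", "crop_damage_elephant"],
        ),
    }
    comparison = pd.DataFrame(
        {"model": list(fits), "aic": [f.aic for f in fits.values()], "log_likelihood": [f.log_likelihood for f in fits.values()]}
    ).sort_values("aic", ignore_index=True)
    return {**fits, "comparison": comparison}
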
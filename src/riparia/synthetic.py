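"""Seeded synthetic landscapes, species pools, surveys, conflict events and
household tables with the statistical structure the downstream analysis assumes.

Every generator is a pure function of its arguments plus an integer seed; no
global random state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from scipy.special import expit
from scipy.stats import truncnorm
from shapely.geometry import LineString, Point

from .covariates import LANDCOVER_CODES, CovariateStack, distance_to_class
from .grids import GridSpec, RasterGrid

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "SpeciesTrait",
    "SurveyParams",
    "HouseholdRecord",
    "HouseholdGenParams",
    "CapacityError",
    "generate_landscape",
    "generate_species_pool",
    "simulate_point_surveys",
    "simulate_conflict_events",
    "simulate_households",
    "households_to_frame",
]

CLASS_NAMES = {v: k for k, v in LANDCOVER_CODES.items()}

THREATENED_CODES = ("VU", "EN", "CR")
NON_THREATENED_CODES = ("LC", "NT", "DD")
DIET_ITEMS = ("invertebrate", "vertebrate", "plant_seed", "other")


class CapacityError(ValueError):
    """The grid (or a mask) is too small for the requested features/points."""


# ---------------------------------------------------------------------------
# landscape


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landcover mosaic."""

    class_proportions: dict = field(
        default_factory=lambda: {
            "forest": 0.30,
            "grassland": 0.20,
            "cropland": 0.44,
            "water": 0.02,
            "settlement": 0.04,
        }
    )
    n_rivers: int = 2
    n_roads: int = 2
    n_villages: int = 6
    smooth_sigma_px: float = 4.0
    plantation_fraction: float = 0.08
    # canopy closure per landcover class: (mean, sd), truncated to [0, 100]
    canopy_by_class: dict = field(
        default_factory=lambda: {
            "forest": (41.0, 16.4),
            "grassland": (8.2, 13.9),
            "cropland": (10.7, 12.9),
            "water": (0.0, 1.0),
            "settlement": (3.0, 4.0),
        }
    )

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.n_rivers < 0:
            raise ValueError("river count must be >= 0")
        if self.n_villages < 1:
            raise ValueError("village count must be >= 1")


@dataclass
class LandscapeBundle:
    """All raster and vector layers of one synthetic landscape."""

    landcover: RasterGrid
    rivers: list
    roads: list
    villages: list
    plantation_mask: RasterGrid
    canopy_closure: RasterGrid
    ndvi: RasterGrid
    pop_density: RasterGrid
    canopy_height: RasterGrid
    seed: int

    @property
    def spec(self) -> GridSpec:
        return self.landcover.spec


def _wandering_line(spec: GridSpec, rng: np.random.Generator, y_frac: float) -> LineString:
    """A polyline traversing the full extent west to east with a random walk in y."""
    res = spec.resolution
    n_steps = spec.n_cols
    xs = np.linspace(spec.origin_x, spec.origin_x + spec.width, n_steps + 1)
    y0 = spec.origin_y - y_frac * spec.height
    steps = rng.normal(0.0, 0.6 * res, n_steps)
    ys = y0 + np.concatenate([[0.0], np.cumsum(steps)])
    ys = np.clip(ys, spec.origin_y - spec.height + 0.5 * res, spec.origin_y - 0.5 * res)
    return LineString(np.column_stack([xs, ys]))


def _burn_line(mask: np.ndarray, spec: GridSpec, line: LineString) -> None:
    """Mark every cell the line passes through (1-pixel rasterization)."""
    step = spec.resolution / 4.0
    n = max(int(np.ceil(line.length / step)), 2)
    pts = [line.interpolate(d) for d in np.linspace(0, line.length, n)]
    x = np.array([p.x for p in pts])
    y = np.array([p.y for p in pts])
    col = np.clip(((x - spec.origin_x) / spec.resolution).astype(int), 0, spec.n_cols - 1)
    row = np.clip(((spec.origin_y - y) / spec.resolution).astype(int), 0, spec.n_rows - 1)
    mask[row, col] = True


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_landscape(spec: GridSpec, config: LandscapeConfig | None = None, seed: int = 0) -> LandscapeBundle:
    """Generate a seeded synthetic landscape bundle.

    Landcover is a smoothed Gaussian random field thresholded at the
    requested class proportions (forest / grassland / cropland), with
    settlements grown around village points, rivers burned in as one-pixel
    polylines (water) and a rectangular plantation block inside cropland.
    """
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    n_pix = spec.n_rows * spec.n_cols

    if config.n_rivers > 0 and spec.n_cols < 2:
        raise CapacityError("grid too narrow to place rivers")
    if config.n_villages > n_pix:
        raise CapacityError("grid too small for the requested villages")

    props = config.class_proportions
    field_total = props["forest"] + props["grassland"] + props["cropland"]
    if field_total <= 0:
        raise ValueError("forest+grassland+cropland proportion must be positive")

    # smoothed random field -> quantile thresholds give (nearly) exact counts
    noise = rng.normal(size=spec.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=config.smooth_sigma_px, mode="reflect")
    p_forest = props["forest"] / field_total
    p_grass = props["grassland"] / field_total
    q1 = np.quantile(smooth, p_forest)
    q2 = np.quantile(smooth, p_forest + p_grass)
    lc = np.full(spec.shape, LANDCOVER_CODES["cropland"], dtype=np.int16)
    lc[smooth <= q1] = LANDCOVER_CODES["forest"]
    lc[(smooth > q1) & (smooth <= q2)] = LANDCOVER_CODES["grassland"]

    # villages and settlement blobs
    village_rows = rng.integers(0, spec.n_rows, config.n_villages)
    village_cols = rng.integers(0, spec.n_cols, config.n_villages)
    vx, vy = spec.cell_center(village_rows, village_cols)
    villages = [Point(x_, y_) for x_, y_ in zip(vx, vy)]
    target_settlement = props["settlement"] * n_pix
    if target_settlement > 0:
        radius_px = max(np.sqrt(target_settlement / (config.n_villages * np.pi)), 0.5)
        rows, cols = np.mgrid[0 : spec.n_rows, 0 : spec.n_cols]
        for r0, c0 in zip(village_rows, village_cols):
            blob = (rows - r0) ** 2 + (cols - c0) ** 2 <= radius_px**2
            lc[blob] = LANDCOVER_CODES["settlement"]

    # rivers traverse the extent west to east; roads likewise (no landcover burn)
    rivers = [_wandering_line(spec, rng, y_frac) for y_frac in np.linspace(0.25, 0.75, config.n_rivers)] if config.n_rivers else []
    water_mask = np.zeros(spec.shape, dtype=bool)
    for line in rivers:
        _burn_line(water_mask, spec, line)
    lc[water_mask] = LANDCOVER_CODES["water"]
    roads = [_wandering_line(spec, rng, y_frac) for y_frac in np.linspace(0.15, 0.9, config.n_roads)] if config.n_roads else []

    landcover = RasterGrid(spec, lc, name="landcover")

    # plantation: rectangular block clipped to cropland
    plantation = np.zeros(spec.shape, dtype=bool)
    crop_rows, crop_cols = np.where(lc == LANDCOVER_CODES["cropland"])
    if config.plantation_fraction > 0 and crop_rows.size:
        side = max(int(np.sqrt(config.plantation_fraction * n_pix)), 1)
        k = rng.integers(0, crop_rows.size)
        r0 = int(np.clip(crop_rows[k] - side // 2, 0, max(spec.n_rows - side, 0)))
        c0 = int(np.clip(crop_cols[k] - side // 2, 0, max(spec.n_cols - side, 0)))
        block = np.zeros(spec.shape, dtype=bool)
        block[r0 : r0 + side, c0 : c0 + side] = True
        plantation = block & (lc == LANDCOVER_CODES["cropland"])
    plantation_mask = RasterGrid(spec, plantation, name="plantation")

    # canopy closure drawn per class from truncated normals
    cc = np.zeros(spec.shape)
    for cls, (mean, sd) in config.canopy_by_class.items():
        m = lc == LANDCOVER_CODES[cls]
        if m.any():
            cc[m] = _truncated_normal(rng, mean, sd, 0.0, 100.0, int(m.sum()))
    canopy_closure = RasterGrid(spec, cc, name="canopy_closure")

    # NDVI correlated with canopy closure, offset per class
    ndvi_base = {"forest": 0.35, "grassland": 0.25, "cropland": 0.20, "water": -0.10, "settlement": 0.05}
    ndvi = np.zeros(spec.shape)
    for cls, base in ndvi_base.items():
        m = lc == LANDCOVER_CODES[cls]
        ndvi[m] = base
    ndvi += 0.004 * cc + rng.normal(0.0, 0.05, spec.shape)
    ndvi = np.clip(ndvi, -1.0, 1.0)
    ndvi_grid = RasterGrid(spec, ndvi, name="ndvi")

    # population density decays away from settlements
    if (lc == LANDCOVER_CODES["settlement"]).any():
        d_set = distance_to_class(landcover, "settlement").values
        pop = 40.0 * np.exp(-d_set / 400.0) + rng.exponential(0.2, spec.shape)
    else:
        pop = np.zeros(spec.shape)
    pop_density = RasterGrid(spec, np.clip(pop, 0.0, None), name="pop_density")

    height = np.clip(0.35 * cc + rng.normal(0.0, 1.5, spec.shape), 0.0, None)
    height[lc == LANDCOVER_CODES["water"]] = 0.0
    canopy_height = RasterGrid(spec, height, name="canopy_height")

    return LandscapeBundle(
        landcover=landcover,
        rivers=rivers,
        roads=roads,
        villages=villages,
        plantation_mask=plantation_mask,
        canopy_closure=canopy_closure,
        ndvi=ndvi_grid,
        pop_density=pop_density,
        canopy_height=canopy_height,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# species pool


@dataclass(frozen=True)
class SpeciesTrait:
    species_id: str
    taxon: str  # "bird" | "mammal"
    diet_fractions: dict
    threat_status: str

    def validate(self) -> None:
        total = sum(self.diet_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"diet fractions of {self.species_id} sum to {total}, not 1")


def generate_species_pool(
    n_birds: int,
    n_mammals: int,
    seed: int = 0,
    dominant_fraction: float = 0.8,
    threatened_fraction: float = 0.2,
) -> list[SpeciesTrait]:
    """Synthetic species traits: diet composition and threat status.

    ``dominant_fraction`` of species get one diet item above 50%;
    ``threatened_fraction`` get a status in {VU, EN, CR}.
    """
    if n_birds < 0 or n_mammals < 0:
        raise ValueError("species counts must be non-negative")
    if n_birds + n_mammals < 1:
        raise ValueError("need at least one species")
    rng = np.random.default_rng(seed)
    pool: list[SpeciesTrait] = []
    taxa = ["bird"] * n_birds + ["mammal"] * n_mammals
    for i, taxon in enumerate(taxa):
        if rng.random() < dominant_fraction:
            dom = rng.integers(0, 3)  # one of the three guild-forming items
            dom_frac = rng.uniform(0.55, 0.95)
            rest = rng.dirichlet(np.ones(3)) * (1.0 - dom_frac)
            fracs = np.insert(rest, dom, dom_frac)
        else:
            fracs = rng.dirichlet(np.ones(4) * 4.0)  # concentrated -> rarely dominant
        fracs = fracs / fracs.sum()
        if rng.random() < threatened_fraction:
            status = str(rng.choice(THREATENED_CODES))
        else:
            status = str(rng.choice(NON_THREATENED_CODES, p=[0.8, 0.15, 0.05]))
        trait = SpeciesTrait(
            species_id=f"{taxon}_{i:03d}",
            taxon=taxon,
            diet_fractions=dict(zip(DIET_ITEMS, fracs.tolist())),
            threat_status=status,
        )
        trait.validate()
        pool.append(trait)
    return pool


# ---------------------------------------------------------------------------
# point surveys


@dataclass(frozen=True)
class SurveyParams:
    """True-model coefficients for the survey simulator."""

    n_locations: int = 120
    # ground temperature ~ intercept + slope * canopy_closure + N(0, sd)
    t_ground_intercept: float = 36.6
    t_ground_slope: float = -0.117
    t_ground_sd: float = 3.7
    # leaf temperature declines nonlinearly; fluorescence rises linearly
    t_leaf_intercept: float = 33.0
    t_leaf_scale: float = 1.2
    t_leaf_sd: float = 1.5
    fluor_intercept: float = 35.0
    fluor_slope: float = 0.12
    fluor_sd: float = 3.0
    # class separation: strength of covariate control on occupancy, per taxon
    class_separation: dict = field(default_factory=lambda: {"mammal": 1.2, "bird": -0.6})
    base_prevalence: tuple = (0.15, 0.5)
    yield_by_crop: dict = field(
        default_factory=lambda: {
            "okra": (55.0, 0.5, 8.0),  # intercept, slope on canopy closure, sd
            "maize": (40.0, 0.8, 6.0),
            "sugarcane": (70.0, 0.0, 10.0),
        }
    )


def simulate_point_surveys(
    bundle: LandscapeBundle,
    stack: CovariateStack,
    pool: list[SpeciesTrait],
    params: SurveyParams | None = None,
    seed: int = 0,
    locations: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate plot microclimate/yield measurements and species detections.

    Returns ``(detections, plots)``: a long location x species table of 0/1
    detections, and a plot table with canopy closure, temperatures,
    fluorescence and (cropland only) crop yields.

    Mammal occupancy rises with percent forest around the location, bird
    occupancy follows its own (default negative) separation coefficient; at
    separation 0 detections are independent of the landscape.
    """
    params = params or SurveyParams()
    rng = np.random.default_rng(seed)
    spec = bundle.spec

    if locations is not None:
        locations = np.asarray(locations, dtype=float)
        xs, ys = locations[:, 0], locations[:, 1]
        spec.index_of(xs, ys)  # raises for out-of-extent points
    else:
        land = bundle.landcover.values != LANDCOVER_CODES["water"]
        rows, cols = np.where(land)
        if rows.size < params.n_locations:
            raise CapacityError("not enough non-water pixels for survey locations")
        k = rng.choice(rows.size, params.n_locations, replace=False)
        xs, ys = spec.cell_center(rows[k], cols[k])

    n = xs.size
    cc = stack["canopy_closure"].sample(xs, ys).astype(float)
    pct_forest = stack["pct_forest_250"].sample(xs, ys).astype(float)
    habitat = np.array([CLASS_NAMES[int(c)] for c in bundle.landcover.sample(xs, ys)])

    plots = pd.DataFrame(
        {
            "location_id": np.arange(n),
            "x": xs,
            "y": ys,
            "habitat": habitat,
            "canopy_closure": cc,
            "t_ground": params.t_ground_intercept
            + params.t_ground_slope * cc
            + rng.normal(0.0, params.t_ground_sd, n),
            "t_leaf": params.t_leaf_intercept
            - params.t_leaf_scale * np.log1p(cc)
            + rng.normal(0.0, params.t_leaf_sd, n),
            "fluorescence": params.fluor_intercept
            + params.fluor_slope * cc
            + rng.normal(0.0, params.fluor_sd, n),
        }
    )
    plots["crop_type"] = None
    plots["yield"] = np.nan
    crop_idx = np.where(habitat == "cropland")[0]
    if crop_idx.size:
        crops = list(params.yield_by_crop)
        assigned = rng.choice(len(crops), crop_idx.size)
        for i, ci in zip(crop_idx, assigned):
            name = crops[ci]
            b0, b1, sd = params.yield_by_crop[name]
            plots.loc[i, "crop_type"] = name
            plots.loc[i, "yield"] = b0 + b1 * cc[i] + rng.normal(0.0, sd)

    # species detections: logistic occupancy on a standardized covariate signal
    def zscore(v):
        s = v.std()
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    signal = {"mammal": zscore(pct_forest), "bird": zscore(cc)}
    rows_out = []
    for sp in pool:
        sep = params.class_separation.get(sp.taxon, 0.0)
        base = rng.uniform(*params.base_prevalence)
        p = expit(np.log(base / (1 - base)) + sep * signal[sp.taxon])
        det = rng.random(n) < p
        rows_out.append(
            pd.DataFrame(
                {
                    "location_id": np.arange(n),
                    "species_id": sp.species_id,
                    "taxon": sp.taxon,
                    "detected": det.astype(int),
                }
            )
        )
    detections = pd.concat(rows_out, ignore_index=True)
    return detections, plots


# ---------------------------------------------------------------------------
# conflict events


def simulate_conflict_events(
    risk_surface: RasterGrid,
    cropland_mask: np.ndarray,
    n_presence: int = 308,
    n_absence: int = 97,
    seed: int = 0,
):
    """Sample crop-raiding presence/absence points on cropland.

    Presence points are drawn (with replacement) with probability
    proportional to the risk surface, absence points proportional to
    ``1 - risk``; defaults emulate a monitoring campaign of 308 presence and
    97 absence events.
    """
    from .pathways import ConflictDataset

    risk = np.asarray(risk_surface.values, dtype=float)
    if np.nanmin(risk) < 0 or np.nanmax(risk) > 1:
        raise ValueError("risk surface values must lie in [0, 1]")
    mask = np.asarray(cropland_mask, dtype=bool)
    rows, cols = np.where(mask)
    if rows.size < n_presence + n_absence:
        raise CapacityError(
            f"only {rows.size} cropland pixels for {n_presence + n_absence} requested points"
        )
    rng = np.random.default_rng(seed)
    r = risk[rows, cols]

    def draw(weights, count):
        total = weights.sum()
        if total <= 0:
            warnings.warn("degenerate sampling weights; falling back to uniform", stacklevel=2)
            weights = np.ones_like(weights)
            total = weights.sum()
        idx = rng.choice(rows.size, size=count, replace=True, p=weights / total)
        return rows[idx], cols[idx]

    pr, pc = draw(r, n_presence)
    ar, ac = draw(1.0 - r, n_absence)
    spec = risk_surface.spec
    px, py = spec.cell_center(pr, pc)
    ax, ay = spec.cell_center(ar, ac)
    frame = pd.DataFrame(
        {
            "x": np.concatenate([px, ax]),
            "y": np.concatenate([py, ay]),
            "outcome": np.concatenate([np.ones(n_presence, dtype=int), np.zeros(n_absence, dtype=int)]),
        }
    )
    return ConflictDataset(frame)


# ---------------------------------------------------------------------------
# households


@dataclass(frozen=True)
class HouseholdRecord:
    household_id: int
    village: str
    respondent_gender: str  # "man" | "woman"
    indicators: dict  # raw indicator values, keyed by indicator name
    crop_damage_wildlife: int
    crop_damage_elephant: int
    perception: int  # ordinal 0-4


DEFAULT_VILLAGES = ("Kidatu", "Mangula", "Mgudeni", "Msalise", "Msolwa", "Sanje")


@dataclass(frozen=True)
class HouseholdGenParams:
    """Generating coefficients for the household simulator."""

    wellbeing_dist: str = "village_normal"  # or "uniform"
    village_wellbeing_means: dict | None = None  # default 0.5 everywhere
    wellbeing_sd: float = 0.15
    gender_wellbeing_effect: float = 0.03  # added for men
    damage_wellbeing_effect: float = 0.0
    indicator_noise_sd: float = 0.08
    p_damage_wildlife: float = 0.30
    p_damage_elephant: float = 0.15
    # proportional-odds perception model
    perception_thresholds: tuple = (-0.5, 0.2, 0.9, 1.9)
    beta_wellbeing: float = 2.43
    beta_woman: float = -0.51
    village_perception_effects: dict | None = None  # default 0 everywhere


def simulate_households(
    n: int = 461,
    villages=DEFAULT_VILLAGES,
    params: HouseholdGenParams | None = None,
    seed: int = 0,
    schema=None,
) -> list[HouseholdRecord]:
    """Generate a synthetic household survey of ``n`` records.

    Wellbeing is drawn per village (or uniformly); the 20 raw indicators are
    generated so that the composite index reconstructs the latent wellbeing
    up to indicator noise; perception follows a cumulative-logit model in
    wellbeing, gender and village.
    """
    from .wellbeing import default_schema

    if n < 1:
        raise ValueError("need at least one household")
    villages = list(villages)
    if not villages:
        raise ValueError("village list must be non-empty")
    params = params or HouseholdGenParams()
    schema = schema or default_schema()
    rng = np.random.default_rng(seed)

    v_means = params.village_wellbeing_means or {}
    v_perc = params.village_perception_effects or {}
    thresholds = np.asarray(params.perception_thresholds, dtype=float)

    records: list[HouseholdRecord] = []
    for i in range(n):
        village = villages[i % len(villages)]
        woman = rng.random() < 0.5
        damage_w = int(rng.random() < params.p_damage_wildlife)
        damage_e = int(rng.random() < params.p_damage_elephant) if damage_w else 0

        if params.wellbeing_dist == "uniform":
            w = rng.uniform(0.0, 1.0)
        else:
            mu = v_means.get(village, 0.5)
            mu += 0.0 if woman else params.gender_wellbeing_effect
            mu += params.damage_wellbeing_effect * damage_w
            w = float(np.clip(rng.normal(mu, params.wellbeing_sd), 0.0, 1.0))

        indicators = {}
        for ind in schema.indicators:
            norm = float(np.clip(w + rng.normal(0.0, params.indicator_noise_sd), 0.0, 1.0))
            if not ind.higher_is_better:
                norm = 1.0 - norm
            indicators[ind.name] = ind.min + norm * (ind.max - ind.min)

        eta = params.beta_wellbeing * w + params.beta_woman * woman + v_perc.get(village, 0.0)
        cum = expit(thresholds - eta)  # P(Y <= j), j = 0..3
        u = rng.random()
        perception = int(np.searchsorted(cum, u))

        records.append(
            HouseholdRecord(
                household_id=i,
                village=village,
                respondent_gender="woman" if woman else "man",
                indicators=indicators,
                crop_damage_wildlife=damage_w,
                crop_damage_elephant=damage_e,
                perception=perception,
            )
        )
    return records


def households_to_frame(records: list[HouseholdRecord]) -> pd.DataFrame:
    """Flatten household records into a table (one indicator per column)."""
    rows = []
    for r in records:
        row = {
            "household_id": r.household_id,
            "village": r.village,
            "respondent_gender": r.respondent_gender,
            "crop_damage_wildlife": r.crop_damage_wildlife,
            "crop_damage_elephant": r.crop_damage_elephant,
            "perception": r.perception,
        }
        row.update(r.indicators)
        rows.append(row)
    return pd.DataFrame(rows)
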
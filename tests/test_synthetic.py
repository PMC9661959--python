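import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, spearmanr

from riparia.covariates import LANDCOVER_CODES, build_stack
from riparia.grids import GridSpec, RasterGrid
from riparia.synthetic import (
    CapacityError,
    HouseholdGenParams,
    LandscapeConfig,
    SurveyParams,
    generate_landscape,
    generate_species_pool,
    households_to_frame,
    simulate_conflict_events,
    simulate_households,
    simulate_point_surveys,
)


def field_proportions(lc):
    """Achieved proportions among forest/grassland/cropland pixels."""
    codes = {c: LANDCOVER_CODES[c] for c in ("forest", "grassland", "cropland")}
    n_field = np.isin(lc, list(codes.values())).sum()
    return {c: (lc == code).sum() / n_field for c, code in codes.items()}


class TestGenerateLandscape:
    def test_deterministic(self, spec):
        a = generate_landscape(spec, seed=7)
        b = generate_landscape(spec, seed=7)
        assert np.array_equal(a.landcover.values, b.landcover.values)
        assert np.array_equal(a.canopy_closure.values, b.canopy_closure.values)
        assert np.array_equal(a.ndvi.values, b.ndvi.values)
        assert all(r1.equals(r2) for r1, r2 in zip(a.rivers, b.rivers))

    def test_all_forest_no_rivers(self, spec):
        cfg = LandscapeConfig(
            class_proportions={"forest": 1.0, "grassland": 0, "cropland": 0, "water": 0, "settlement": 0},
            n_rivers=0,
            n_roads=0,
            plantation_fraction=0.0,
        )
        b = generate_landscape(spec, cfg, seed=1)
        assert np.all(b.landcover.values == LANDCOVER_CODES["forest"])
        assert b.rivers == []

    def test_proportions_100(self):
        cfg = LandscapeConfig()
        b = generate_landscape(GridSpec(100, 100), cfg, seed=1)
        achieved = field_proportions(b.landcover.values)
        total = sum(cfg.class_proportions[c] for c in achieved)
        for c, got in achieved.items():
            want = cfg.class_proportions[c] / total
            assert abs(got - want) <= 0.10 * want

    def test_proportions_converge_200(self):
        cfg = LandscapeConfig()
        b = generate_landscape(GridSpec(200, 200), cfg, seed=3)
        achieved = field_proportions(b.landcover.values)
        total = sum(cfg.class_proportions[c] for c in achieved)
        for c, got in achieved.items():
            want = cfg.class_proportions[c] / total
            assert abs(got - want) <= 0.05 * want

    def test_bad_proportions(self, spec):
        cfg = LandscapeConfig(class_proportions={"forest": 0.5, "grassland": 0.2, "cropland": 0.2, "water": 0.0, "settlement": 0.0})
        with pytest.raises(ValueError, match="sum to 1"):
            generate_landscape(spec, cfg, seed=1)

    def test_capacity_errors(self):
        with pytest.raises(CapacityError):
            generate_landscape(GridSpec(1, 1), LandscapeConfig(n_rivers=1), seed=1)
        with pytest.raises(CapacityError):
            generate_landscape(GridSpec(2, 2), LandscapeConfig(n_rivers=0, n_villages=50), seed=1)

    def test_bundle_invariants(self, bundle):
        cc = bundle.canopy_closure.values
        assert cc.min() >= 0 and cc.max() <= 100
        assert np.all(np.abs(bundle.ndvi.values) <= 1)
        assert bundle.pop_density.values.min() >= 0
        assert bundle.canopy_height.values.min() >= 0
        lc = bundle.landcover.values
        forest_mean = cc[lc == LANDCOVER_CODES["forest"]].mean()
        crop_mean = cc[lc == LANDCOVER_CODES["cropland"]].mean()
        assert forest_mean > crop_mean

    def test_rivers_traverse_and_water_on_rivers(self, bundle):
        spec = bundle.spec
        for river in bundle.rivers:
            x0, _, x1, _ = river.bounds
            assert x0 <= spec.origin_x + 1e-6
            assert x1 >= spec.origin_x + spec.width - 1e-6
        # every water pixel's cell square intersects a river line
        import shapely
        from shapely.geometry import box

        merged = shapely.union_all(bundle.rivers)
        rows, cols = np.where(bundle.landcover.values == LANDCOVER_CODES["water"])
        res = spec.resolution
        for r, c in zip(rows, cols):
            cx, cy = spec.cell_center(r, c)
            assert box(cx - res / 2, cy - res / 2, cx + res / 2, cy + res / 2).intersects(merged)


class TestSpeciesPool:
    def test_counts(self):
        pool = generate_species_pool(0, 5, seed=7)
        assert len(pool) == 5
        assert all(sp.taxon == "mammal" for sp in pool)

    def test_diet_fractions_sum_to_one(self):
        for sp in generate_species_pool(20, 20, seed=3):
            assert abs(sum(sp.diet_fractions.values()) - 1.0) < 1e-9

    def test_threatened_fraction(self):
        pool = generate_species_pool(25, 25, seed=11, threatened_fraction=0.2)
        n_threat = sum(sp.threat_status in ("VU", "EN", "CR") for sp in pool)
        assert 4 <= n_threat <= 17  # ~10 expected of 50

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            generate_species_pool(-1, 5, seed=0)
        with pytest.raises(ValueError):
            generate_species_pool(0, 0, seed=0)


class TestPointSurveys:
    def test_noise_free_linear(self, bundle, stack):
        pool = generate_species_pool(2, 2, seed=0)
        params = SurveyParams(t_ground_sd=0.0, t_ground_slope=-0.117, t_ground_intercept=36.6)
        _, plots = simulate_point_surveys(bundle, stack, pool, params, seed=4)
        expect = 36.6 - 0.117 * plots["canopy_closure"]
        assert np.allclose(plots["t_ground"], expect)

    def test_deterministic(self, bundle, stack):
        pool = generate_species_pool(3, 3, seed=0)
        d1, p1 = simulate_point_surveys(bundle, stack, pool, seed=9)
        d2, p2 = simulate_point_surveys(bundle, stack, pool, seed=9)
        pd.testing.assert_frame_equal(d1, d2)
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_separation_independence(self):
        b = generate_landscape(GridSpec(80, 80), seed=5)
        stk = build_stack(b)
        pool = generate_species_pool(0, 10, seed=1)
        params = SurveyParams(n_locations=500, class_separation={"mammal": 0.0, "bird": 0.0})
        det, plots = simulate_point_surveys(b, stk, pool, params, seed=2)
        rich = det.groupby("location_id")["detected"].sum()
        pct = stk["pct_forest_250"].sample(plots["x"].to_numpy(), plots["y"].to_numpy())
        rich_bin = pd.qcut(rich.rank(method="first"), 3, labels=False)
        pct_bin = pd.qcut(pd.Series(pct).rank(method="first"), 3, labels=False)
        _, p, *_ = chi2_contingency(pd.crosstab(rich_bin, pct_bin))
        assert p > 0.01

    def test_positive_separation_forest_richness(self):
        b = generate_landscape(GridSpec(80, 80), seed=5)
        stk = build_stack(b)
        pool = generate_species_pool(0, 10, seed=1)
        params = SurveyParams(n_locations=400, class_separation={"mammal": 1.5, "bird": 0.0})
        det, plots = simulate_point_surveys(b, stk, pool, params, seed=2)
        rich = det.groupby("location_id")["detected"].sum().to_numpy()
        pct = stk["pct_forest_250"].sample(plots["x"].to_numpy(), plots["y"].to_numpy())
        rho, p = spearmanr(rich, pct)
        assert rho > 0.2 and p < 1e-4

    def test_out_of_extent_locations(self, bundle, stack):
        pool = generate_species_pool(1, 1, seed=0)
        bad = np.array([[-1e6, 1e6]])
        with pytest.raises(ValueError, match="outside"):
            simulate_point_surveys(bundle, stack, pool, seed=0, locations=bad)


class TestConflictEvents:
    def _risk(self, spec, values):
        return RasterGrid(spec, values, name="risk")

    def test_default_counts(self, bundle, stack):
        from scipy.special import expit

        risk = stack["dist_forest"].like(expit(1.2 - stack["dist_forest"].values / 250.0))
        cropland = bundle.landcover.values == LANDCOVER_CODES["cropland"]
        ds = simulate_conflict_events(risk, cropland, seed=1)
        assert ds.n_presence == 308
        assert ds.n_absence == 97

    def test_flat_risk_equal_means(self, spec):
        risk = self._risk(spec, np.full(spec.shape, 0.5))
        mask = np.ones(spec.shape, bool)
        ds = simulate_conflict_events(risk, mask, 100, 100, seed=3)
        f = ds.frame
        rp = risk.sample(f.loc[f.outcome == 1, "x"].to_numpy(), f.loc[f.outcome == 1, "y"].to_numpy())
        ra = risk.sample(f.loc[f.outcome == 0, "x"].to_numpy(), f.loc[f.outcome == 0, "y"].to_numpy())
        assert rp.mean() == ra.mean() == 0.5

    def test_degenerate_single_pixel(self, spec):
        vals = np.zeros(spec.shape)
        vals[10, 20] = 1.0
        ds = simulate_conflict_events(self._risk(spec, vals), np.ones(spec.shape, bool), 10, 5, seed=0)
        pres = ds.frame[ds.frame.outcome == 1]
        cx, cy = spec.cell_center(10, 20)
        assert np.all(pres["x"] == cx) and np.all(pres["y"] == cy)

    def test_presence_concentrated_on_high_risk(self, spec, rng):
        vals = rng.uniform(0, 1, spec.shape)
        risk = self._risk(spec, vals)
        ds = simulate_conflict_events(risk, np.ones(spec.shape, bool), 300, 100, seed=5)
        f = ds.frame
        rp = risk.sample(f.loc[f.outcome == 1, "x"].to_numpy(), f.loc[f.outcome == 1, "y"].to_numpy())
        ra = risk.sample(f.loc[f.outcome == 0, "x"].to_numpy(), f.loc[f.outcome == 0, "y"].to_numpy())
        assert rp.mean() > ra.mean()

    def test_capacity_error(self, spec):
        mask = np.zeros(spec.shape, bool)
        mask[0, :5] = True
        with pytest.raises(CapacityError):
            simulate_conflict_events(self._risk(spec, np.full(spec.shape, 0.5)), mask, 10, 5, seed=0)

    def test_risk_bounds_validated(self, spec):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_conflict_events(self._risk(spec, np.full(spec.shape, 1.5)), np.ones(spec.shape, bool), 5, 5)


class TestHouseholds:
    def test_default_counts_and_villages(self):
        recs = simulate_households(seed=1)
        assert len(recs) == 461
        assert len({r.village for r in recs}) == 6
        assert all(r.perception in range(5) for r in recs)
        assert all(len(r.indicators) == 20 for r in recs)

    def test_zero_wellbeing_coefficient(self):
        from riparia.wellbeing import composite_index, default_schema, normalize_indicators

        params = HouseholdGenParams(beta_wellbeing=0.0, beta_woman=0.0, wellbeing_dist="uniform")
        recs = simulate_households(2000, params=params, seed=2)
        hh = households_to_frame(recs)
        schema = default_schema()
        idx = composite_index(normalize_indicators(hh, schema), schema)
        rho, _ = spearmanr(idx["index"], hh["perception"])
        assert abs(rho) < 0.06

    def test_degenerate_thresholds(self):
        params = HouseholdGenParams(perception_thresholds=(np.inf, np.inf, np.inf, np.inf))
        recs = simulate_households(50, params=params, seed=0)
        assert {r.perception for r in recs} == {0}

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            simulate_households(0)
        with pytest.raises(ValueError):
            simulate_households(10, villages=[])

    def test_indicators_within_declared_ranges(self):
        from riparia.wellbeing import default_schema

        schema = default_schema()
        recs = simulate_households(100, seed=3)
        lims = {i.name: (i.min, i.max) for i in schema.indicators}
        for r in recs:
            for name, val in r.indicators.items():
                lo, hi = lims[name]
                assert lo <= val <= hi
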
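import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from riparia.covariates import LANDCOVER_CODES, build_stack, extract_at_points
from riparia.grids import GridSpec
from riparia.pathways import (
    ConflictDataset,
    classify_guild,
    fit_pathway1,
    fit_pathway2,
    fit_pathway3,
    flag_threatened,
    map_predictions,
    predict_risk,
    richness_classes,
)
from riparia.synthetic import SpeciesTrait, generate_landscape, simulate_conflict_events


def trait(**fracs):
    full = {"invertebrate": 0.0, "vertebrate": 0.0, "plant_seed": 0.0, "other": 0.0}
    full.update(fracs)
    return SpeciesTrait("sp", "bird", full, "LC")


class TestGuildAndThreat:
    def test_dominant_item(self):
        assert classify_guild(trait(plant_seed=0.6, invertebrate=0.4)) == "plant_seed"

    def test_exact_half_is_none(self):
        assert classify_guild(trait(plant_seed=0.5, invertebrate=0.5)) == "none"

    def test_pure_diet(self):
        assert classify_guild(trait(invertebrate=1.0)) == "invertebrate"

    def test_other_dominant_is_none(self):
        assert classify_guild(trait(other=0.7, invertebrate=0.3)) == "none"

    def test_invalid_fractions(self):
        with pytest.raises(ValueError, match="sum"):
            classify_guild(trait(invertebrate=0.6))

    @pytest.mark.parametrize("status,expect", [("EN", True), ("VU", True), ("CR", True), ("LC", False), ("NT", False), ("DD", False)])
    def test_flag_threatened(self, status, expect):
        assert flag_threatened(status) is expect

    def test_unknown_status(self):
        with pytest.raises(ValueError, match="unknown"):
            flag_threatened("XX")

    def test_pool_classification_order_independent(self, rng):
        from riparia.synthetic import generate_species_pool

        pool = generate_species_pool(10, 10, seed=4)
        guilds = {sp.species_id: classify_guild(sp) for sp in pool}
        shuffled = list(pool)
        rng.shuffle(shuffled)
        assert {sp.species_id: classify_guild(sp) for sp in shuffled} == guilds


class TestRichnessClasses:
    def test_tertiles_balanced(self):
        labels, thr = richness_classes(np.arange(1, 10), n_classes=3)
        assert (labels == "low").sum() == (labels == "medium").sum() == (labels == "high").sum() == 3
        assert len(thr) == 2

    def test_all_equal_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            richness_classes(np.full(10, 4.0), n_classes=3)

    def test_two_point_split(self):
        labels, _ = richness_classes(np.array([0, 10]), n_classes=2)
        assert labels.tolist() == ["low", "high"]

    def test_ties_to_lower_class(self):
        labels, thr = richness_classes(np.array([1.0, 2.0, 2.0, 3.0]), n_classes=2)
        # threshold is the median (2.0); ties are not "high"
        assert labels.tolist() == ["low", "low", "low", "high"]


class TestPathway1:
    def _plots(self, rng, n=70, sd=1.0):
        cc = rng.uniform(0, 60, n)
        return pd.DataFrame(
            {
                "canopy_closure": cc,
                "t_ground": 36.6 - 0.117 * cc + rng.normal(0, sd, n),
                "t_leaf": 33.0 - 1.2 * np.log1p(cc) + rng.normal(0, 0.5, n),
                "fluorescence": 35 + 0.12 * cc + rng.normal(0, 1, n),
                "crop_type": rng.choice(["maize", "okra"], n),
                "yield": 40 + 0.5 * cc + rng.normal(0, 5, n),
            }
        )

    def test_linear_response_glm_negative_slope(self, rng):
        fits = fit_pathway1(self._plots(rng))
        f = fits["t_ground"]
        assert f.model_type == "glm"
        assert f.fit.slope < 0

    def test_noise_free_perfect_fit(self, rng):
        plots = self._plots(rng, sd=0.0)
        plots["t_ground"] = 36.6 - 0.117 * plots["canopy_closure"]
        fits = fit_pathway1(plots)
        assert fits["t_ground"].fit.deviance_explained == pytest.approx(1.0)

    def test_yield_fit_per_crop_and_skip(self, rng, caplog):
        plots = self._plots(rng)
        plots.loc[plots["crop_type"] == "okra", "yield"] = np.nan  # okra has no yields
        import logging

        with caplog.at_level(logging.INFO, logger="riparia.pathways"):
            fits = fit_pathway1(plots)
        assert "yield_maize" in fits
        assert "yield_okra" not in fits

    def test_missing_column_schema_error(self, rng):
        plots = self._plots(rng).drop(columns=["fluorescence"])
        with pytest.raises(KeyError, match="fluorescence"):
            fit_pathway1(plots)


@pytest.fixture(scope="module")
def p2_setup():
    """One informative covariate separating two richness classes."""
    rng = np.random.default_rng(8)
    n = 120
    informative = rng.normal(size=n)
    noise1 = rng.normal(size=n)
    noise2 = rng.normal(size=n)
    labels = np.where(informative + rng.normal(0, 0.6, n) > 0, "high", "low")
    responses = pd.DataFrame({"metric_id": "mammals_high", "location_id": np.arange(n), "label": labels})
    pts = pd.DataFrame(
        {
            "location_id": np.arange(n),
            "x": rng.uniform(0, 3000, n),
            "y": -rng.uniform(0, 3000, n),
            "informative": informative,
            "noise1": noise1,
            "noise2": noise2,
        }
    )
    return responses, pts


class TestPathway2:
    def test_informative_covariate_selected(self, p2_setup):
        responses, pts = p2_setup
        fits = fit_pathway2(responses, pts)
        model = fits["mammals_high"].model
        assert model.covariate_names == ["informative"]

    def test_posterior_monotone_along_gradient(self, p2_setup):
        from riparia.stats import predict_lda

        responses, pts = p2_setup
        fits = fit_pathway2(responses, pts)
        model = fits["mammals_high"].model
        grid = np.linspace(-3, 3, 50)[:, None]
        post = predict_lda(model, grid)
        hi = list(model.class_labels).index("high")
        assert np.all(np.diff(post[:, hi]) > 0)

    def test_single_class_metric_skipped(self, p2_setup):
        responses, pts = p2_setup
        degenerate = pd.DataFrame({"metric_id": "birds_high", "location_id": np.arange(len(pts)), "label": "high"})
        fits = fit_pathway2(pd.concat([responses, degenerate]), pts)
        assert fits["skipped"] == {"birds_high": "single observed class"}

    def test_raster_probabilities_normalized(self, bundle, stack, p2_setup):
        responses, pts = p2_setup
        fits = fit_pathway2(responses, pts)
        # rename the model covariate to a real stack layer for mapping
        model = fits["mammals_high"].model
        model.covariate_names = ["ndvi"]
        rasters = map_predictions(model, stack)
        total = sum(r.values for r in rasters.values())
        assert np.allclose(total[~np.isnan(total)], 1.0, atol=1e-9)

    def test_moran_reported(self, p2_setup):
        responses, pts = p2_setup
        fits = fit_pathway2(responses, pts)
        assert fits["mammals_high"].moran is not None

    def test_residual_moran_calibrated_on_iid_fits(self):
        from riparia.pathways import _lda_pipeline

        nonsig = 0
        n_rep = 100
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            n = 60
            cov = pd.DataFrame({c: rng.normal(size=n) for c in "abc"})
            labels = np.where(cov["a"] + rng.normal(0, 1, n) > 0, "high", "low")
            coords = rng.uniform(0, 1000, (n, 2))
            fit = _lda_pipeline("m", labels, cov, coords, p_enter=0.05)
            nonsig += fit.moran is not None and fit.moran.p_value >= 0.05
        assert nonsig >= 0.9 * n_rep


@pytest.fixture(scope="module")
def conflict_setup():
    bundle = generate_landscape(GridSpec(80, 80), seed=5)
    stack = build_stack(bundle)
    risk = stack["dist_forest"].like(expit(1.5 - stack["dist_forest"].values / 150.0))
    cropland = bundle.landcover.values == LANDCOVER_CODES["cropland"]
    ds = simulate_conflict_events(risk, cropland, 308, 97, seed=3)
    pts = extract_at_points(stack, ds.frame["x"], ds.frame["y"]).drop(columns=["point_id"])
    return bundle, stack, ds, pts


class TestPathway3:
    def test_forest_distance_drives_selection(self, conflict_setup):
        _, _, ds, pts = conflict_setup
        fit = fit_pathway3(ds, pts)
        assert any("forest" in c for c in fit.model.covariate_names)

    def test_risk_raster_bounds(self, conflict_setup):
        _, stack, ds, pts = conflict_setup
        fit = fit_pathway3(ds, pts)
        risk = predict_risk(fit, stack).values
        ok = risk[~np.isnan(risk)]
        assert ok.min() >= 0.0 and ok.max() <= 1.0

    def test_flat_risk_null_auc(self, conflict_setup):
        bundle, stack, _, _ = conflict_setup
        flat = stack["ndvi"].like(np.full(bundle.spec.shape, 0.5))
        cropland = bundle.landcover.values == LANDCOVER_CODES["cropland"]
        ds = simulate_conflict_events(flat, cropland, 308, 97, seed=9)
        pts = extract_at_points(stack, ds.frame["x"], ds.frame["y"]).drop(columns=["point_id"])
        fit = fit_pathway3(ds, pts, p_enter=0.05)
        from riparia.stats import predict_lda

        post = predict_lda(fit.model, pts[fit.model.covariate_names].to_numpy(float))
        p_pres = post[:, list(fit.model.class_labels).index("presence")]
        y = ds.frame["outcome"].to_numpy()
        # rank-based AUC
        order = np.argsort(p_pres)
        ranks = np.empty_like(order, dtype=float)
        ranks[order] = np.arange(1, len(y) + 1)
        auc = (ranks[y == 1].sum() - 308 * 309 / 2) / (308 * 97)
        assert abs(auc - 0.5) < 0.1

    def test_single_class_error(self, conflict_setup):
        _, _, ds, pts = conflict_setup
        frame = ds.frame.copy()
        frame["outcome"] = 1
        with pytest.raises(ValueError, match="presence and absence"):
            fit_pathway3(ConflictDataset(frame), pts)


class TestDirectionalConsistency:
    def test_high_class_probability_tracks_forest_gain(self):
        """End-to-end: richness driven by pct_forest_250 -> scenario predictions
        rise wherever the scenario raised pct_forest_250."""
        from riparia.scenario import apply_riparian_buffer, rebuild_scenario_stack
        from riparia.stats import predict_lda

        rng = np.random.default_rng(12)
        bundle = generate_landscape(GridSpec(80, 80), seed=12)
        stack = build_stack(bundle)
        n = 150
        rows = rng.integers(0, 80, n)
        cols = rng.integers(0, 80, n)
        x, y = bundle.spec.cell_center(rows, cols)
        pct = stack["pct_forest_250"].sample(x, y)
        labels = np.where(pct + rng.normal(0, 10, n) > np.median(pct), "high", "low")
        responses = pd.DataFrame({"metric_id": "m", "location_id": np.arange(n), "label": labels})
        pts = pd.DataFrame({"location_id": np.arange(n), "x": x, "y": y, "pct_forest_250": pct})
        fits = fit_pathway2(responses, pts, covariate_names=["pct_forest_250"])
        model = fits["m"].model

        scen_lc = apply_riparian_buffer(bundle.landcover, bundle.rivers)
        scen = rebuild_scenario_stack(bundle, stack, scen_lc)
        base_p = map_predictions(model, stack)["high"].values
        scen_p = map_predictions(model, scen)["high"].values
        gained = scen["pct_forest_250"].values > stack["pct_forest_250"].values
        assert gained.any()
        assert np.all(scen_p[gained] >= base_p[gained] - 1e-12)
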
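"""End-to-end pipeline driver: simulate -> covariates -> fit -> scenario ->
predict -> report, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import change as chg
from . import pathways as pw
from . import synthetic as syn
from .config import PipelineConfig
from .covariates import LANDCOVER_CODES, build_stack, extract_at_points
from .io import write_geojson_lines, write_raster
from .scenario import apply_riparian_buffer, rebuild_scenario_stack

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PIPELINE_STAGES"]

PIPELINE_STAGES = ("simulate", "covariates", "fit", "scenario", "predict", "report")


def _record(manifest, path: Path):
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["outputs"][str(path.name)] = digest


def _true_risk(stack):
    """Generating risk surface for conflict events: high near forest."""
    d = stack["dist_forest"].values
    return stack["dist_forest"].like(expit(1.2 - d / 250.0), name="true_risk")


def run_pipeline(config: PipelineConfig, out_dir, stages=PIPELINE_STAGES) -> dict:
    """Run the pipeline through the requested stages, writing every output
    under ``out_dir``; returns the manifest (also written as manifest.json).

    Stages are cumulative: a later stage implies all earlier ones (inputs
    are regenerated deterministically from the seeded config).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    last = max(PIPELINE_STAGES.index(s) for s in stages)
    manifest: dict = {"config_hash": config.hash(), "seeds": dict(config.seeds), "stages": [], "outputs": {}}

    def wants(stage):
        return PIPELINE_STAGES.index(stage) <= last

    def run_stage(name, fn):
        try:
            result = fn()
        except Exception as e:
            manifest["failed_stage"] = name
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        manifest["stages"].append(name)
        return result

    # --- simulate -----------------------------------------------------------
    def stage_simulate():
        bundle = syn.generate_landscape(config.grid, config.landscape, seed=config.seeds["landscape"])
        for layer_name in ("landcover", "canopy_closure", "ndvi", "pop_density", "canopy_height"):
            p = write_raster(out / f"{layer_name}.asc", getattr(bundle, layer_name))
            _record(manifest, p)
        p = write_raster(out / "plantation_mask.asc", bundle.plantation_mask.like(bundle.plantation_mask.values.astype(float)))
        _record(manifest, p)
        for vec_name in ("rivers", "roads", "villages"):
            p = write_geojson_lines(out / f"{vec_name}.geojson", getattr(bundle, vec_name))
            _record(manifest, p)
        return bundle

    bundle = run_stage("simulate", stage_simulate)
    if not wants("covariates"):
        return _finish(manifest, out)

    # --- covariates ---------------------------------------------------------
    def stage_covariates():
        stack = build_stack(bundle)
        for name, layer in stack.layers.items():
            p = write_raster(out / f"cov_{name}.asc", layer)
            _record(manifest, p)
        return stack

    stack = run_stage("covariates", stage_covariates)
    if not wants("fit"):
        return _finish(manifest, out)

    # --- fit ----------------------------------------------------------------
    def stage_fit():
        pool = syn.generate_species_pool(config.n_birds, config.n_mammals, seed=config.seeds["species"])
        detections, plots = syn.simulate_point_surveys(bundle, stack, pool, seed=config.seeds["surveys"])
        plots.to_csv(out / "plots.csv", index=False)
        _record(manifest, out / "plots.csv")
        detections.to_csv(out / "detections.csv", index=False)
        _record(manifest, out / "detections.csv")

        p1 = pw.fit_pathway1(plots)
        pd.DataFrame(
            [
                {
                    "response": k,
                    "model": f.model_type,
                    "anova_p": f.anova_p,
                    "n": f.n,
                    "deviance_explained": f.fit.deviance_explained,
                }
                for k, f in p1.items()
            ]
        ).to_csv(out / "pathway1_fits.csv", index=False)
        _record(manifest, out / "pathway1_fits.csv")

        # pathway-2 responses: richness classes per taxon + threatened presence
        responses = []
        threatened = {sp.species_id for sp in pool if pw.flag_threatened(sp.threat_status)}
        for taxon in ("bird", "mammal"):
            sub = detections[detections["taxon"] == taxon]
            rich = sub.groupby("location_id")["detected"].sum()
            try:
                labels, _ = pw.richness_classes(rich.to_numpy(), n_classes=3)
                responses.append(
                    pd.DataFrame({"metric_id": f"{taxon}s_high", "location_id": rich.index, "label": labels})
                )
            except ValueError as e:
                log.warning("richness classes for %s skipped: %s", taxon, e)
            thr = sub[sub["species_id"].isin(threatened)].groupby("location_id")["detected"].max()
            responses.append(
                pd.DataFrame(
                    {
                        "metric_id": f"{taxon}s_threatened",
                        "location_id": thr.index,
                        "label": np.where(thr.to_numpy() > 0, "present", "absent"),
                    }
                )
            )
        responses = pd.concat(responses, ignore_index=True)
        pts = extract_at_points(stack, plots["x"], plots["y"], plots["location_id"]).rename(
            columns={"point_id": "location_id"}
        )
        p2 = pw.fit_pathway2(responses, pts, p_enter=config.p_enter)

        # pathway 3: conflict points from a forest-proximity risk surface
        cropland = bundle.landcover.values == LANDCOVER_CODES["cropland"]
        conflict = syn.simulate_conflict_events(
            _true_risk(stack), cropland, config.n_presence, config.n_absence, seed=config.seeds["conflict"]
        )
        conflict.frame.to_csv(out / "conflict_points.csv", index=False)
        _record(manifest, out / "conflict_points.csv")
        cpts = extract_at_points(stack, conflict.frame["x"], conflict.frame["y"]).drop(columns=["point_id"])
        p3 = pw.fit_pathway3(conflict, cpts, p_enter=config.p_enter)

        # household survey + wellbeing models
        from . import wellbeing as wb

        households = syn.simulate_households(config.n_households, seed=config.seeds["households"])
        hh = syn.households_to_frame(households)
        hh.to_csv(out / "households.csv", index=False)
        _record(manifest, out / "households.csv")
        schema = wb.default_schema()
        idx = wb.composite_index(wb.normalize_indicators(hh, schema), schema)
        damage = wb.damage_effects_model(
            idx["index"], hh["crop_damage_wildlife"], hh["crop_damage_elephant"], hh["respondent_gender"], hh["village"]
        )
        percep = wb.perception_model(
            hh["perception"], idx["index"], hh["respondent_gender"], hh["village"],
            hh["crop_damage_wildlife"], hh["crop_damage_elephant"],
        )
        damage["comparison"].to_csv(out / "wellbeing_damage_models.csv", index=False)
        _record(manifest, out / "wellbeing_damage_models.csv")
        percep["comparison"].to_csv(out / "perception_models.csv", index=False)
        _record(manifest, out / "perception_models.csv")

        diag_rows = []
        for metric, fit in {**{k: v for k, v in p2.items() if k != "skipped"}, "crop_raiding": p3}.items():
            diag_rows.append(
                {
                    "metric_id": metric,
                    "selected": ";".join(fit.model.covariate_names),
                    "n": fit.n,
                    "moran_I": fit.moran.I if fit.moran else np.nan,
                    "moran_p": fit.moran.p_value if fit.moran else np.nan,
                }
            )
            (out / f"model_{metric}.json").write_text(fit.model.to_json())
            _record(manifest, out / f"model_{metric}.json")
        pd.DataFrame(diag_rows).to_csv(out / "model_diagnostics.csv", index=False)
        _record(manifest, out / "model_diagnostics.csv")
        return {"pool": pool, "plots": plots, "p1": p1, "p2": p2, "p3": p3}

    fits = run_stage("fit", stage_fit)
    if not wants("scenario"):
        return _finish(manifest, out)

    # --- scenario -----------------------------------------------------------
    def stage_scenario():
        scen_lc = apply_riparian_buffer(bundle.landcover, bundle.rivers, config.scenario)
        scen_stack = rebuild_scenario_stack(bundle, stack, scen_lc, config.scenario)
        p = write_raster(out / "landcover_scenario.asc", scen_lc)
        _record(manifest, p)
        converted = pd.DataFrame(
            {
                "class": list(LANDCOVER_CODES),
                "pixels_converted": [
                    int(((bundle.landcover.values == code) & (scen_lc.values != code)).sum())
                    for code in LANDCOVER_CODES.values()
                ],
            }
        )
        converted.to_csv(out / "scenario_conversion_audit.csv", index=False)
        _record(manifest, out / "scenario_conversion_audit.csv")
        return scen_lc, scen_stack

    scen_lc, scen_stack = run_stage("scenario", stage_scenario)
    if not wants("predict"):
        return _finish(manifest, out)

    # --- predict ------------------------------------------------------------
    def stage_predict():
        preds = {}
        p2 = fits["p2"]
        for metric, fit in p2.items():
            if metric == "skipped":
                continue
            for provenance, stk in (("baseline", stack), ("scenario", scen_stack)):
                for cls, raster in pw.map_predictions(fit.model, stk).items():
                    key = f"{metric}_{cls}_{provenance}"
                    preds[key] = raster
                    p = write_raster(out / f"pred_{key}.asc", raster)
                    _record(manifest, p)
        for provenance, stk in (("baseline", stack), ("scenario", scen_stack)):
            risk = pw.predict_risk(fits["p3"], stk)
            preds[f"risk_{provenance}"] = risk
            p = write_raster(out / f"pred_risk_{provenance}.asc", risk)
            _record(manifest, p)
        return preds

    preds = run_stage("predict", stage_predict)
    if not wants("report"):
        return _finish(manifest, out)

    # --- report -------------------------------------------------------------
    def stage_report():
        plots = fits["plots"]
        mask = chg.high_risk_change_mask(preds["risk_baseline"], preds["risk_scenario"])
        p = write_raster(out / "risk_change_mask.asc", mask.like(mask.values.astype(float)))
        _record(manifest, p)
        (out / "risk_change_legend.json").write_text(json.dumps(chg.CHANGE_CODES))
        _record(manifest, out / "risk_change_legend.json")

        units = pd.DataFrame(
            {"unit": "plot", "unit_id": plots["location_id"].astype(str), "x": plots["x"], "y": plots["y"]}
        )
        hab_units = units.assign(unit="habitat", unit_id=plots["habitat"].to_numpy())
        lc = bundle.landcover.values
        smallholder = (lc == LANDCOVER_CODES["cropland"]) & ~bundle.plantation_mask.values.astype(bool)
        prod_units = []
        for name, m in (("smallholder", smallholder), ("plantation", bundle.plantation_mask.values.astype(bool))):
            n_pts = min(config.n_production_points, int(m.sum()))
            if n_pts == 0:
                prod_units.append(pd.DataFrame({"unit": ["production_system"], "unit_id": [name], "x": [np.nan], "y": [np.nan]}))
                continue
            x, y = chg.sample_random_points(bundle.landcover.like(m), n_pts, seed=config.seeds["scenario"])
            prod_units.append(pd.DataFrame({"unit": "production_system", "unit_id": name, "x": x, "y": y}))
        all_units = pd.concat([units, hab_units, *prod_units], ignore_index=True).dropna(subset=["x"])

        metric_pairs = {}
        for key in preds:
            if key.endswith("_baseline"):
                stem = key[: -len("_baseline")]
                if f"{stem}_scenario" in preds:
                    metric_pairs[stem] = (preds[key], preds[f"{stem}_scenario"])
        table = chg.aggregate_change(metric_pairs, all_units)
        table.to_csv(out / "change_table.csv", index=False)
        _record(manifest, out / "change_table.csv")

        summary = chg.habitat_summary(plots, "canopy_closure")
        summary["summary"].to_csv(out / "habitat_summary_canopy.csv", index=False)
        _record(manifest, out / "habitat_summary_canopy.csv")
        return table

    run_stage("report", stage_report)
    return _finish(manifest, out)


def _finish(manifest: dict, out: Path) -> dict:
    blob = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
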
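# riparia

Evaluate riparian tree-restoration scenarios in forest–agricultural
landscapes. The package chains five stages:

1. **Synthetic landscape** (`riparia.synthetic`) — seeded generators for a
   five-class landcover mosaic (forest, grassland, cropland, water,
   settlement) with rivers, roads, villages, a plantation block, canopy
   closure, NDVI, population density and canopy height; plus species trait
   pools, plot/point surveys, crop-raiding presence/absence events and a
   461-household wellbeing survey.
2. **Covariate engine** (`riparia.covariates`) — the 18-layer predictor
   stack: Euclidean distances (forest, river, road, settlement, plantation),
   percent forest in a 250 m window, focal mean/sd of NDVI and canopy
   closure in 150 m and 500 m windows, and base layers. Windows are circular
   on pixel centres with the focal pixel included; distances are exact
   pixel-centre Euclidean.
3. **Scenario engine** (`riparia.scenario`) — converts every convertible
   pixel within 60 m (configurable) of a river centreline to forest, imputes
   canopy closure and NDVI on new forest from the current-forest empirical
   distribution, and rebuilds the forest-derived stack layers.
4. **Statistics & pathways** (`riparia.stats`, `riparia.pathways`,
   `riparia.wellbeing`) — Wilks' Lambda with greedy forward selection,
   linear discriminant models with posterior raster mapping, Gaussian
   GLM vs cubic-spline smooth with ANOVA model choice, Moran's I residual
   diagnostics, proportional-odds ordinal regression, random-intercept
   mixed models, diet-guild/threat classifiers, richness-class construction
   and the equal-dimension-weight composite wellbeing index.
5. **Change report** (`riparia.change`) — delta rasters, the p > 0.5
   high-risk change mask, seeded random point samples per production
   system, multi-scale change tables and habitat summaries with ANOVA +
   Tukey HSD.

## Spatial conventions

One planar grid per session: origin at the top-left corner, x east / y
north in metres, 30 m default resolution, values sampled at pixel centres.
Rasters are read/written as ESRI ASCII grids (`.asc`, plain text); vectors
as GeoJSON. No CRS handling — all inputs must share the grid.

## CLI

```bash
riparia all --out out/run --seed 1                 # full pipeline, default config
riparia all --config config.yaml --out out/run     # explicit config
riparia simulate --out out/sim --seed 3            # single stage (earlier stages
riparia scenario --out out/scn --seed 3            #  are regenerated from seeds)
```

Minimal `config.yaml`:

```yaml
grid: {n_rows: 100, n_cols: 100, resolution: 30.0}
scenario: {buffer_half_width: 60.0, attribute_imputation: mean, seed: 1}
seeds: {landscape: 1, species: 1, surveys: 1, conflict: 1, households: 1, scenario: 1}
```

Every stage writes its outputs plus `manifest.json` (config hash, seeds,
sha256 of every output file); identical configs give identical manifests.

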
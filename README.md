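# urbancanopy

Sub-pixel urban tree-canopy temperature analysis on synthetic city scenes.

Urban trees buffer city heat, but moderate-resolution thermal satellites
(~70 m) cannot resolve individual canopies: every pixel mixes trees, grass,
roofs, roads and water. This package implements, and verifies end-to-end on
synthetic scenes with known ground truth, the full analysis chain for
recovering city-wide canopy temperature and explaining its spatial pattern:

1. **Sub-pixel unmixing** (`urbancanopy.decompose`). A pixel's
   emissivity-weighted radiance budget is
   `ε·LST⁴ = Σₖ εₖ fₖ Tₖ⁴ + r` over 8 surface classes. Assuming each
   element has one temperature within a 350 m neighborhood, a 5×5 moving
   window yields a linear system in `xₖ = Tₖ⁴`, solved by bounded linear
   least squares (trust-region reflective) with `t_min⁴ ≤ xₖ ≤ t_max⁴`
   from the domain's observed LST range.
2. **Spatial anomalies** (`urbancanopy.anomalies`).
   `ΔLST_canopy = LST_canopy − mean(LST over land)`, one scalar reference
   per overpass, so acquisitions from different days compose into a
   pseudo-diurnal cycle.
3. **Diurnal summaries** (`urbancanopy.diurnal`). Spatial mean/STD per
   overpass, canopy-vs-element contrasts, zonal means.
4. **GAM attribution** (`urbancanopy.gam`). At 350 m resolution,
   `Δ ~ s(GAF,k=6) + s(DTW,k=6) + s(BH,k=3) + ti(GAF,DTW) + ti(DTW,BH) +
   s(x,y)` with penalized splines (REML, via R's mgcv), where GAF is green
   area fraction, DTW distance to bluespace (km), BH area-weighted building
   height (m). Each covariate's **maximum temperature effect (MTE)** is the
   max−min predicted anomaly over its range.
5. **Synthetic scenes** (`urbancanopy.scene`). A generator with known,
   recorded ground truth: categorical land cover at 7 m aggregated to
   fractions at 70 m, diurnal per-class temperatures, injected greenspace /
   bluespace / building-height effects, and observation noise.

See `docs/methods.md` for model details, assumptions and limitations.

## Worked example

```python
import urbancanopy as uc

cfg = uc.SceneConfig(grid_rows=100, grid_cols=100, seed=1)
truth, fractions, covariates, overpasses = uc.build_scene_products(cfg)

lst = overpasses[7]                      # the 13:00 overpass
stack = uc.decompose_image(lst, fractions, cfg.class_emissivities)
canopy = uc.canopy_map(stack, fractions)
ref = uc.domain_mean(lst, ~truth.water_mask)
delta = uc.anomaly_map(canopy, ref, lst.overpass_local_time)
print(uc.spatial_stats(delta))           # (mean, STD, n) of the anomaly
```

The numbered drivers under `analysis/` run the whole study and print what
they find; on the default scene (seed 1):

```
$ python analysis/02_decompose.py
midday per-element recovery (window fraction >= 0.1):
  tree_canopy        RMSE 0.87 K bias -0.14 K (n=3123)
  building           RMSE 0.38 K bias -0.01 K (n=4506)
  road               RMSE 0.97 K bias +0.33 K (n=7938)
  ...
kernel sensitivity (overall RMSE vs truth):
  kernel 3: RMSE 0.54 K, 9604 solves
  kernel 5: RMSE 0.33 K, 10000 solves
  ...

$ python analysis/03_diurnal_summary.py
diurnal canopy anomaly summary:
  daytime STD peak   0.81 K
  nighttime STD mean 0.47 K
  midday mean anomaly -3.60 K
  midday contrast vs building           +5.11 K
  midday contrast vs grass_shrub        +2.23 K
  ...

$ python analysis/04_gam_attribution.py
day: n=163 neighborhoods, deviance explained 0.64
daytime MTEs (K) and shares (%):
  gaf: 0.85 K (18.9%)
  dtw: 2.62 K (58.2%)
  bh: 1.04 K (23.0%)
nighttime BH MTE: 1.09 K (sign flips day to night)
```

Reading these numbers: element temperatures are recovered to well under
1 K despite 0.5 K observation noise; canopy anomalies vary several times
more by day than by night; trees are cooler than the surrounding man-made
surfaces, most strongly at midday; greenspace and bluespace cool the canopy
by day while tall buildings cool it by day (shade) and warm it at night
(reduced sky view). Tables land in `results/`, large rasters in `scratch/`.

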
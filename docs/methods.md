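# Methods

This package reconstructs, on fully synthetic scenes with known ground
truth, a city-scale analysis of urban tree-canopy surface temperature: a
moderate-resolution thermal image is decomposed into per-element surface
temperatures, the tree-canopy component is expressed as a spatial anomaly,
its diurnal behaviour is summarized, and its spatial variation is attributed
to neighborhood covariates with generalized additive models (GAMs).

## The mixing model and its inversion

A thermal pixel at ~70 m mixes radiance from the surface elements it
contains.  With class emissivities ε_k, areal fractions f_k and element
temperatures T_k, the emissivity-weighted quartic-temperature budget of
pixel (i,j) is

    ε(i,j) · LST(i,j)⁴ = Σ_k ε_k · f_k(i,j) · T_k(i,j)⁴ + r(i,j),

where ε(i,j) = Σ_k f_k ε_k and r collects noise and model error.  Within a
small neighborhood (350 m, i.e. a 5×5 pixel window) each element is assumed
to have a single temperature.  Stacking the window's pixels gives a linear
system in the unknowns x_k = T_k⁴ with design A[p,k] = ε_k f_k(p) and target
y[p] = ε(p)·LST(p)⁴, solved as a box-constrained linear least-squares
problem (trust-region reflective) with t_min⁴ ≤ x_k ≤ t_max⁴.  The bounds
default to the domain's min/max observed LST per image.  The window slides
with stride 1 and each solution is assigned to the window's center pixel;
border windows shrink and are solved while ≥ 8 valid pixels remain.

Numerical choices:

- Variables are scaled by t_max⁴ before solving; the unconstrained solution
  is computed first (QR/SVD least squares) and accepted when feasible — it
  is then the exact constrained optimum — falling back to the bounded TRF
  solver only when a bound is violated.
- Classes whose summed fraction over the window is below
  `min_fraction` (default 0.02) of the window area are unidentifiable and
  return NaN.  Raising this cutoff is counter-productive: a dropped but
  present class's radiance aliases into the remaining coefficients.
- Rank-deficient designs are repaired by iteratively dropping the class
  with the smallest summed fraction (deterministic order), with a flag.
- Each pixel carries a condition bitmask (low-fraction drop, rank
  deficiency, active bound, unsolved).  Exactness guarantees apply to
  cleanly flagged windows: with window-constant truth, no noise and a
  full-rank design, recovery is exact to machine precision (~1e-12 K).
  Windows containing sliver classes retain a small aliasing bias
  (~0.01–0.1 K) in the other classes.

Two systematic effects of the bound rule are worth knowing.  Because a
mixed pixel's LST is a quartic mean, the observed LST range is strictly
inside the element-temperature range, so the domain rule slightly
under-brackets the hottest and coolest elements and truncates their
estimate distributions (a censoring bias of order a few tenths of a Kelvin
when an element sits at the domain extreme).  Second, weakly present
classes inherit part of the window-mean signal, drawing their estimates
toward the window average; regressing estimated on true canopy anomalies
on the default scene gives a slope of ~0.8.

## Anomalies and diurnal summaries

The canopy map is the tree-class solution where the pixel's own tree
fraction is ≥ 0.05.  The anomaly ΔLST_canopy subtracts a single scalar per
overpass — the arithmetic mean LST over land pixels (water and nodata
excluded) of the original image, not of the decomposed product — which
removes day-to-day weather offsets when overpasses from different days are
arranged into a pseudo-diurnal cycle.  Summaries use the population STD
(fixed for determinism; immaterial at n ≈ 10⁴).  Day/night labels come from
per-overpass sunrise/sunset metadata.  Element contrasts are pixelwise
T_element − T_canopy over co-solved pixels, unweighted by fraction.

## GAM attribution

At the 5×5-pixel neighborhood scale the anomaly block mean (over valid
canopy pixels) is modeled as

    Δ ~ s(GAF, k=6) + s(DTW, k=6) + s(BH, k=3) + ti(GAF,DTW) + ti(DTW,BH)
        + s(x, y, k=10 city / k=2 zone),

with penalized thin-plate splines, smoothing parameters by REML, each
overpass fitted independently.  Basis dimensions are deliberately small so
the curves capture city-scale trends; the zone-level spatial smooth is
nearly planar.  Fitting is delegated to mgcv through an Rscript subprocess;
the module exposes the curves, term table and diagnostics in Python.
Covariates: GAF is the tree+grass block-mean fraction; DTW the Euclidean
distance (km) from the block-center pixel to the nearest bluespace
component larger than 500 m² (8-connected, center-to-center); BH the
area-weighted mean building height, weighting heights by footprint within
the block and dividing by built area (an alternative total-area convention
is exposed as a switch).

The maximum temperature effect (MTE) of a covariate is max − min of the
model prediction over a stated covariate range, holding the other
covariates at their medians and the spatial smooth at the domain centroid;
requested ranges outside the data support are clipped with a warning.
Predictions are precomputed on a dense grid at fit time and interpolated,
so MTE extraction needs no second fit.  Effect shares (MTE_i / Σ MTE_j) are
a ranking device, not a variance decomposition.

## The synthetic scene generator

The generator emulates a coastal summer city on a 70 m grid, each pixel
subdivided 10× for the categorical land-cover map.  Smoothed, thresholded
Gaussian fields produce contiguous water bodies, parks (tree/grass mosaics)
and built blocks at a ~350 m patch scale — the park/block scale the
neighborhood analysis is designed around — overlaid with a street grid
(14–21 m wide, 160–260 m spacing, deliberately incommensurate with the
pixel size so per-pixel road fractions vary the way a real block structure
intersects a sensor grid).  Building heights are log-normal-ish and
spatially clustered; fractions come from exact sub-pixel counting.

Element temperatures follow a per-class diurnal cycle (half-sine solar
forcing between sunrise and sunset): at the midday peak, man-made classes
sit ~2.8–3.9 K above the tree canopy, grass +0.5 K, water −1 K; at night
the spread collapses (roads +1.4 K, water +1.3 K, buildings +0.4 K).  The
tree-canopy field additionally carries the injected covariate effects,
evaluated on the 5×5 box mean of the pixel covariates (the same 350 m
scale the attribution uses):

- greenspace: slope −4 K per unit GAF, daytime (scaled by solar weight);
- bluespace: −2 K · exp(−DTW / 0.5 km), daytime;
- building height: −0.45 K·log1p(BH) by day, +0.33 K·log1p(BH) by night.

Each effect field is centered to zero scene mean: base class temperatures
are citywide means and effects redistribute them spatially, which is what
an anomaly-based analysis observes (all gradients, STDs and MTEs are
gauge-invariant).  Every class also gets spatially correlated texture
(0.3 K sd, ~700 m correlation — twice the solve window, so the shared-
temperature hypothesis approximately holds), and the composed LST receives
0.5 K Gaussian observation noise, a typical thermal-sensor figure.  All
randomness derives from a single seed; fixed seeds give bit-identical
scenes.

What the generator does not emulate: atmospheric and directional-emissivity
effects, cloud masking, geolocation error, sea-breeze dynamics, within-class
emissivity variation, and tree-species or tree-height structure.  Passing
tests therefore demonstrate correctness of the inversion, bookkeeping and
statistical machinery under the model's own assumptions — not retrieval
accuracy on real imagery.

Two sampling effects make pipeline-level effect estimates smaller than the
injected slopes, on synthetic and real data alike: canopy pixels in
low-greenness neighborhoods sit at locally greener spots (so the observable
response range is compressed), and the solver's pull toward the window mean
attenuates anomaly amplitudes by ~0.8.  The covariate-level recovery
experiments — where the response is constructed directly from the
neighborhood covariates — isolate the statistical machinery and recover the
injected magnitudes within ~10%.

## Problem sizes and defaults

The study scene is 100×100 pixels (7×7 km) with 12 overpasses at ~2 h
spacing; recovery experiments use 60×60 (noise robustness, 10 seeds),
250×250 (noise-free exactness) and 160×160 (GAM recovery, ~1000
neighborhoods, 5 seeds).  Defaults: kernel 5, min_fraction 0.02, canopy
fraction threshold 0.05, bluespace area filter 500 m², neighborhood block
5 pixels, solver tolerance 1e-12 on scaled variables.

## Known limitations

- Class emissivities are class-constant; per-pixel class emissivity is not
  modeled (standard simplification; configurable).
- The domain min/max bound rule censors elements at the domain extremes
  (see above); widen the bounds explicitly when element temperatures are
  expected to reach beyond the observed LST range.
- Effect shares have no unique definition from GAM fits; the reported
  shares are MTE ratios and should be read as a ranking.
- DTW is evaluated at block centers, not averaged over tree locations
  within the block.
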
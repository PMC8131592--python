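"""Synthetic urban thermal scenes with known ground truth.

Builds a fine-scale categorical land-cover map (contiguous parks, water
bodies, built blocks) from thresholded smoothed random fields, aggregates it
to class fractions at the thermal-pixel scale (~70 m), assigns each surface
class a diurnally varying element temperature, injects known covariate
effects into the tree-canopy field, and composes the mixed-pixel LST image
through the emissivity-weighted T⁴ mixing relation.  Every injected effect
is recorded so downstream recovery can be scored against truth.

Default effect magnitudes emulate a summer mid-latitude coastal city:
man-made surfaces a few K warmer than canopy at midday and slightly warmer
at night, water cooler than canopy by day and warmer at night, a strong
daytime greenspace cooling gradient, an exponential nearshore cooling within
~0.5 km of bluespace, and a building-height effect that cools by day
(shadowing) and warms at night (reduced sky view).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .classes import DEFAULT_EMISSIVITY, N_CLASSES, SURFACE_CLASSES, TREE, WATER
from .georef import GridGeoref
from .raster import CovariateGrids, FractionStack, LSTRaster, aggregate_fractions, \
    area_weighted_bh, distance_to_bluespace

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "inject_truth_temperatures",
    "forward_compose",
    "build_scene_products",
    "diurnal_weight",
]

#: Element temperature at night and at the diurnal peak (K), per class.
#: Offsets vs. tree canopy mirror typical urban midday/night contrasts:
#: buildings ~+3.9 K, other impervious ~+3.1 K, roads ~+2.8 K, grass ~+0.5 K
#: at the peak; roads ~+1.4 K, other impervious ~+1.0 K, buildings ~+0.4 K,
#: water ~+1.3 K at night.
BASE_NIGHT_K: dict[str, float] = {
    "tree_canopy": 291.0,
    "grass_shrub": 291.3,
    "bare_earth": 291.6,
    "water": 292.3,
    "building": 291.4,
    "road": 292.4,
    "other_impervious": 292.0,
    "railroad": 292.0,
}
BASE_PEAK_K: dict[str, float] = {
    "tree_canopy": 303.0,
    "grass_shrub": 303.5,
    "bare_earth": 305.2,
    "water": 302.0,
    "building": 306.9,
    "road": 305.8,
    "other_impervious": 306.1,
    "railroad": 306.0,
}


@dataclass
class SceneConfig:
    """Parameters of a synthetic scene.

    Pixels are ``cell_size``-metre squares; each is subdivided into
    ``subpixel_factor``² fine cells for the categorical land-cover map.
    Effect coefficients are the ground-truth covariate effects injected into
    the tree-canopy temperature field (daytime effects scale with the solar
    weight, the building-height night effect with its complement).
    """

    grid_rows: int = 100
    grid_cols: int = 100
    subpixel_factor: int = 10
    cell_size: float = 70.0
    class_emissivities: np.ndarray = field(
        default_factory=lambda: DEFAULT_EMISSIVITY.copy()
    )
    overpass_times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 13.0,
                                       15.0, 18.0, 20.0, 22.0)
    sunrise: float = 6.0
    sunset: float = 20.0
    gaf_slope: float = -4.0  # K per unit green fraction, daytime
    dtw_amplitude: float = -2.0  # K at the shoreline, daytime
    dtw_length_scale: float = 0.5  # km
    bh_day_coeff: float = -0.45  # K per log1p(m), daytime shadowing
    bh_night_coeff: float = 0.33  # K per log1p(m), nocturnal sky-view warming
    texture_sigma: float = 0.3  # K, spatially correlated within-class texture
    texture_length_pixels: float = 10.0  # ~2x the solve window, so the
    # shared-temperature hypothesis of the unmixing approximately holds
    effect_smoothing_pixels: int = 5  # covariate effects act on the 5x5-pixel
    # (350 m) neighborhood box mean, the same scale the attribution uses
    noise_sigma: float = 0.5  # K, additive observation noise on LST
    patch_length_pixels: float = 5.0  # land-cover patch scale (~350 m), the
    # park/block size the neighborhood analysis scale is chosen to capture
    truth_tile: int | None = None  # if set, element temps constant per tile
    seed: int = 0

    def __post_init__(self) -> None:
        eps = np.asarray(self.class_emissivities, dtype=float)
        if eps.shape != (N_CLASSES,) or np.any(eps <= 0) or np.any(eps > 1):
            raise ValueError("class_emissivities must be 8 values in (0, 1]")
        self.class_emissivities = eps
        if self.subpixel_factor < 1:
            raise ValueError("subpixel_factor must be >= 1")
        if self.noise_sigma < 0 or self.texture_sigma < 0:
            raise ValueError("noise levels must be non-negative")
        if self.dtw_length_scale <= 0 or self.patch_length_pixels <= 0:
            raise ValueError("length scales must be positive")


@dataclass
class SceneTruth:
    """Ground truth for one synthetic scene."""

    class_map: np.ndarray  # fine-grid categorical
    bh_grid: np.ndarray  # pixel-scale area-weighted building height (m)
    water_mask: np.ndarray  # pixel-scale (fraction > 0.5)
    dtw_grid: np.ndarray  # km
    gaf_grid: np.ndarray
    georef: GridGeoref
    true_element_temps: dict[float, np.ndarray] = field(default_factory=dict)
    injected_effects: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    degenerate_classes: tuple[int, ...] = ()


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field: smoothed white noise, restandardized."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / max(f.std(), 1e-12)


def diurnal_weight(t: float, sunrise: float, sunset: float) -> float:
    """Solar-forcing proxy in [0, 1]: half-sine over daylight, 0 at night."""
    if not (sunrise < t < sunset):
        return 0.0
    return float(np.sin(np.pi * (t - sunrise) / (sunset - sunrise)))


def generate_scene(config: SceneConfig):
    """Generate the static part of a scene.

    Returns ``(truth, fractions, bh_grid, water_mask, dtw_grid)``.  The fine
    class map is built from thresholded smoothed random fields so parks,
    water bodies and built blocks form contiguous patches; fractions come
    from sub-pixel counting.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    f = config.subpixel_factor
    fine_shape = (config.grid_rows * f, config.grid_cols * f)
    sigma_fine = config.patch_length_pixels * f

    water_f = _smooth_field(rng, fine_shape, sigma_fine * 1.6)
    green_f = _smooth_field(rng, fine_shape, sigma_fine)
    treegrass_f = _smooth_field(rng, fine_shape, sigma_fine * 0.6)
    built_f = _smooth_field(rng, fine_shape, sigma_fine * 0.5)
    minor_f = _smooth_field(rng, fine_shape, sigma_fine * 0.35)

    class_map = np.empty(fine_shape, dtype=np.int8)
    is_water = water_f > np.quantile(water_f, 0.93)
    remaining = ~is_water
    green_cut = np.quantile(green_f[remaining], 0.68)
    is_green = remaining & (green_f > green_cut)
    is_tree = is_green & (treegrass_f > np.quantile(treegrass_f[is_green], 0.38))
    is_grass = is_green & ~is_tree
    is_built_area = remaining & ~is_green

    # partition the built area into the five non-green land classes
    b = built_f[is_built_area]
    q = np.quantile(b, [0.40, 0.68, 0.78, 0.90])
    built_codes = np.digitize(built_f, q)  # 0..4 bands
    # band 0: building, 1: road, 2: bare earth, 3: other impervious, 4: railroad
    band_to_class = np.array([4, 5, 2, 6, 7], dtype=np.int8)
    # thin railroad corridors and bare lots further with the minor field
    class_map[:] = 0
    class_map[is_built_area] = band_to_class[built_codes[is_built_area]]
    swap = is_built_area & (band_to_class[built_codes] == 7) & (minor_f < 0)
    class_map[swap] = 6
    class_map[is_tree] = TREE
    class_map[is_grass] = 1

    # street grid: straight streets ~160 m and ~260 m apart, 2-3 fine cells
    # (14-21 m) wide, skipping most park interiors and all water.  Spacings
    # deliberately incommensurate with the pixel size so the per-pixel road
    # fraction varies from pixel to pixel, the way a real block structure
    # intersects a sensor grid.
    rr, cc = np.indices(fine_shape)
    sp_r, sp_c = round(3.1 * f), round(5.3 * f)
    off_r, off_c = rng.integers(0, sp_r), rng.integers(0, sp_c)
    road_lines = ((rr + off_r) % sp_r < 3) | ((cc + off_c) % sp_c < 5)
    road_lines &= ~(is_green & (minor_f < 0.3))
    class_map[road_lines] = 5
    class_map[is_water] = WATER

    georef_fine = GridGeoref(0.0, 0.0, config.cell_size / f)
    fractions = aggregate_fractions(class_map, f, georef_fine)

    # building heights: log-normal-ish, spatially clustered, on built cells only
    h_field = _smooth_field(rng, fine_shape, sigma_fine * 0.8)
    built_mask_fine = class_map == 4
    bh_fine = np.where(built_mask_fine, np.exp(2.6 + 0.9 * h_field), 0.0)
    bh_grid = area_weighted_bh(bh_fine, built_mask_fine, f)

    water_mask = fractions.fractions[WATER] > 0.5
    dtw_grid = distance_to_bluespace(water_mask, config.cell_size)
    gaf_grid = fractions.green_area_fraction()

    truth = SceneTruth(
        class_map=class_map,
        bh_grid=bh_grid,
        water_mask=water_mask,
        dtw_grid=dtw_grid,
        gaf_grid=gaf_grid,
        georef=GridGeoref(0.0, 0.0, config.cell_size),
        degenerate_classes=fractions.degenerate_classes,
    )
    return truth, fractions, bh_grid, water_mask, dtw_grid


def _tile_mean(field: np.ndarray, tile: int) -> np.ndarray:
    """Replace a field by its mean over non-overlapping tile×tile blocks."""
    r, c = field.shape
    rt, ct = r // tile, c // tile
    out = field.copy()
    blocks = field[: rt * tile, : ct * tile].reshape(rt, tile, ct, tile)
    means = blocks.mean(axis=(1, 3))
    out[: rt * tile, : ct * tile] = np.repeat(np.repeat(means, tile, 0), tile, 1)
    return out


def inject_truth_temperatures(
    truth: SceneTruth, config: SceneConfig, overpass: float
) -> np.ndarray:
    """Build per-class true temperature fields (8, rows, cols) for one overpass.

    Each class gets its diurnal base temperature plus spatially correlated
    texture; the tree-canopy field additionally carries the injected
    covariate effects: daytime greenspace cooling (linear in GAF), daytime
    nearshore cooling (exponential in DTW), and a building-height term that
    cools by day and warms at night.  All effect fields are recorded on the
    truth object.  With ``truth_tile`` set, fields are made constant on
    tile×tile pixel blocks (block means), giving truth that exactly matches
    the window-constancy assumption of the unmixing.
    """
    shape = truth.bh_grid.shape
    w = diurnal_weight(overpass, config.sunrise, config.sunset)
    rng = np.random.default_rng([config.seed, int(round(overpass * 10)), 7])

    dtw = truth.dtw_grid
    dtw_decay = np.exp(-np.where(np.isfinite(dtw), dtw, np.inf)
                       / config.dtw_length_scale)
    # effects act at the neighborhood scale: a moving box mean of the pixel
    # covariates, so at block centers the injected effect is an exact
    # function of the block-mean covariate the attribution stage uses
    s = int(config.effect_smoothing_pixels)
    if s > 1:
        gaf_n = ndimage.uniform_filter(truth.gaf_grid, s)
        log_bh = ndimage.uniform_filter(np.log1p(truth.bh_grid), s)
    else:
        gaf_n = truth.gaf_grid
        log_bh = np.log1p(truth.bh_grid)

    # each effect is centered over the scene: the class base temperature is
    # the citywide mean and effects redistribute it spatially, which is the
    # quantity an anomaly-based analysis observes (gradients, STDs and MTEs
    # are invariant to this gauge)
    def centered(field: np.ndarray) -> np.ndarray:
        return field - field.mean()

    gaf_effect = w * config.gaf_slope * centered(gaf_n)
    dtw_effect = w * config.dtw_amplitude * centered(dtw_decay)
    bh_effect = (w * config.bh_day_coeff
                 + (1.0 - w) * config.bh_night_coeff) * centered(log_bh)

    temps = np.empty((N_CLASSES,) + shape)
    texture_amp = config.texture_sigma
    for k, name in enumerate(SURFACE_CLASSES):
        base = BASE_NIGHT_K[name] + (BASE_PEAK_K[name] - BASE_NIGHT_K[name]) * w
        tex = texture_amp * _smooth_field(rng, shape, config.texture_length_pixels) \
            if texture_amp > 0 else np.zeros(shape)
        temps[k] = base + tex
    temps[TREE] = temps[TREE] + gaf_effect + dtw_effect + bh_effect

    if config.truth_tile:
        for k in range(N_CLASSES):
            temps[k] = _tile_mean(temps[k], config.truth_tile)

    truth.true_element_temps[overpass] = temps
    truth.injected_effects[overpass] = {
        "gaf": gaf_effect, "dtw": dtw_effect, "bh": bh_effect,
        "solar_weight": np.full((), w),
    }
    return temps


def forward_compose(
    element_temps: np.ndarray,
    fractions: FractionStack,
    class_emissivities: np.ndarray,
    noise_sigma: float,
    seed: int | np.random.Generator,
    georef: GridGeoref | None = None,
    overpass_local_time: float = 12.0,
    nodata_mask: np.ndarray | None = None,
) -> LSTRaster:
    """Compose a mixed-pixel LST image from element temperatures.

    The pixel radiance is the fraction- and emissivity-weighted sum of
    element T⁴; the pixel emissivity is the fraction-weighted mean of class
    emissivities, so LST = [Σₖ εₖ fₖ Tₖ⁴ / ε_pixel]^¼.  Gaussian observation
    noise (sd ``noise_sigma`` K) is then added to LST.
    """
    f = fractions.fractions
    eps = np.asarray(class_emissivities, dtype=float)
    eps_pixel = np.einsum("k,krc->rc", eps, f)
    radiance = np.einsum("k,krc,krc->rc", eps, f, element_temps**4)
    radicand = radiance / eps_pixel
    assert np.all(radicand[np.isfinite(radicand)] >= 0), "negative T^4 radicand"
    lst = radicand**0.25
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        lst = lst + rng.normal(0.0, noise_sigma, lst.shape)
    if nodata_mask is None:
        nodata_mask = np.zeros(lst.shape, dtype=bool)
    lst = np.where(nodata_mask, np.nan, lst)
    return LSTRaster(
        lst=lst,
        emissivity=np.where(nodata_mask, np.nan, eps_pixel),
        nodata_mask=nodata_mask,
        georef=georef or fractions.georef or GridGeoref(0.0, 0.0, 70.0),
        overpass_local_time=overpass_local_time,
    )


def build_scene_products(config: SceneConfig):
    """Generate a full multi-overpass scene: truth, fractions, covariates,
    and one LSTRaster per overpass time.  One-stop entry point for the
    analysis drivers and recovery experiments."""
    truth, fractions, bh_grid, water_mask, dtw_grid = generate_scene(config)
    rows, cols = truth.bh_grid.shape
    zone_rows, zone_cols = 2, 3
    zi = (np.arange(rows)[:, None] * zone_rows // rows) * zone_cols \
        + (np.arange(cols)[None, :] * zone_cols // cols)
    covariates = CovariateGrids(
        gaf=truth.gaf_grid, dtw=dtw_grid, bh=bh_grid,
        zone_id=np.broadcast_to(zi, (rows, cols)).copy(),
    )
    overpasses = []
    noise_rng = np.random.default_rng([config.seed, 101])
    for t in config.overpass_times:
        temps = inject_truth_temperatures(truth, config, t)
        lst = forward_compose(
            temps, fractions, config.class_emissivities,
            config.noise_sigma, noise_rng,
            georef=truth.georef, overpass_local_time=t,
        )
        overpasses.append(lst)
    return truth, fractions, covariates, overpasses
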
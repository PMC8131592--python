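"""Raster containers and covariate derivation.

Holds the thermal image (LST + emissivity), the 8-class fraction stack, and
the neighborhood covariates the attribution stage uses: green-area fraction
(GAF), Euclidean distance to bluespace (DTW), and area-weighted mean
building height (BH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .classes import GRASS, N_CLASSES, TREE
from .georef import GridGeoref

__all__ = [
    "LSTRaster",
    "FractionStack",
    "CovariateGrids",
    "aggregate_fractions",
    "area_weighted_bh",
    "distance_to_bluespace",
]


@dataclass
class LSTRaster:
    """One thermal overpass: per-pixel LST (K) and emissivity, plus metadata."""

    lst: np.ndarray
    emissivity: np.ndarray
    nodata_mask: np.ndarray
    georef: GridGeoref
    overpass_local_time: float
    acquisition_date: str = ""

    def __post_init__(self) -> None:
        if self.lst.shape != self.emissivity.shape or self.lst.shape != self.nodata_mask.shape:
            raise ValueError("lst, emissivity and nodata_mask shapes must match")
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.lst[valid])):
            raise ValueError("LST must be finite where unmasked")
        eps = self.emissivity[valid]
        if np.any((eps <= 0) | (eps > 1)):
            raise ValueError("emissivity must be in (0, 1] where unmasked")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lst.shape


@dataclass
class FractionStack:
    """Per-pixel areal fractions of the 8 surface classes (bands sum to 1)."""

    fractions: np.ndarray
    georef: GridGeoref | None = None
    degenerate_classes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        f = self.fractions
        if f.ndim != 3 or f.shape[0] != N_CLASSES:
            raise ValueError(f"fractions must be ({N_CLASSES}, rows, cols)")
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        sums = f.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("fractions must sum to 1 per pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.fractions.shape[1:]

    def green_area_fraction(self) -> np.ndarray:
        """GAF: tree + grass cover fraction."""
        return self.fractions[TREE] + self.fractions[GRASS]


@dataclass
class CovariateGrids:
    """Attribution covariates co-registered with the thermal grid."""

    gaf: np.ndarray
    dtw: np.ndarray  # km
    bh: np.ndarray  # m
    zone_id: np.ndarray

    def __post_init__(self) -> None:
        if not (self.gaf.shape == self.dtw.shape == self.bh.shape == self.zone_id.shape):
            raise ValueError("covariate grid shapes must match")
        if np.any(self.gaf > 1 + 1e-9) or np.any(self.gaf < -1e-9):
            raise ValueError("gaf must lie in [0, 1]")
        if np.any(self.bh < 0):
            raise ValueError("bh must be non-negative")


def _blockify(fine: np.ndarray, factor: int) -> np.ndarray:
    """Reshape a fine grid into (rows, cols, factor*factor) blocks, cropping
    trailing cells (with a warning) if dimensions do not divide evenly."""
    fr, fc = fine.shape
    rows, cols = fr // factor, fc // factor
    if rows == 0 or cols == 0:
        raise ValueError("raster smaller than one aggregation block")
    if fr % factor or fc % factor:
        warnings.warn(
            f"fine raster {fine.shape} not divisible by factor {factor}; cropping",
            stacklevel=3,
        )
        fine = fine[: rows * factor, : cols * factor]
    return fine.reshape(rows, factor, cols, factor).transpose(0, 2, 1, 3).reshape(
        rows, cols, factor * factor
    )


def aggregate_fractions(
    class_map: np.ndarray, factor: int, georef: GridGeoref | None = None
) -> FractionStack:
    """Aggregate a fine categorical raster to class fractions by sub-pixel
    counting: fraction of class k = (# fine cells of class k in the
    factor×factor block) / factor².
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    codes = np.unique(class_map)
    bad = codes[(codes < 0) | (codes >= N_CLASSES)]
    if bad.size:
        raise ValueError(f"unknown class code(s) {bad.tolist()} in class map")
    blocks = _blockify(np.asarray(class_map), factor)
    rows, cols, n = blocks.shape
    fractions = np.empty((N_CLASSES, rows, cols))
    for k in range(N_CLASSES):
        fractions[k] = (blocks == k).sum(axis=2) / n
    degenerate = tuple(
        int(k) for k in range(N_CLASSES) if not np.any(fractions[k] > 0)
    )
    coarse_ref = None
    if georef is not None:
        coarse_ref = GridGeoref(georef.x0, georef.y0, georef.cell * factor)
    return FractionStack(fractions, coarse_ref, degenerate)


def area_weighted_bh(
    bh_fine: np.ndarray,
    built_mask: np.ndarray,
    factor: int,
    *,
    weight_by_total_area: bool = False,
) -> np.ndarray:
    """Area-weighted mean building height per aggregation block.

    The mean weights building heights by their footprint area within the
    block and divides by the built area (cells where ``built_mask``), so a
    lone tall building in a mostly-open block keeps its height.  Pass
    ``weight_by_total_area=True`` to divide by the whole block area instead.
    Blocks with no built cells get 0.
    """
    bh_fine = np.asarray(bh_fine, dtype=float)
    if np.any(bh_fine[np.asarray(built_mask, bool)] < 0):
        raise ValueError("building heights must be non-negative")
    hblocks = _blockify(np.where(built_mask, bh_fine, 0.0), factor)
    mblocks = _blockify(np.asarray(built_mask, dtype=float), factor)
    total = hblocks.sum(axis=2)
    if weight_by_total_area:
        return total / hblocks.shape[2]
    built = mblocks.sum(axis=2)
    with np.errstate(invalid="ignore"):
        out = np.where(built > 0, total / np.maximum(built, 1e-300), 0.0)
    return out


def distance_to_bluespace(
    water_mask: np.ndarray,
    cell_size: float,
    min_area_m2: float = 500.0,
) -> np.ndarray:
    """Euclidean distance (km) from each cell center to the nearest center of
    a qualifying bluespace cell.

    Connected water components (8-connectivity) with area <= ``min_area_m2``
    are discarded before the distance transform, mirroring the exclusion of
    sub-500 m² ponds and fountains.  Water cells of qualifying bluespaces
    have distance 0.  If no qualifying water remains the grid is +inf and a
    warning is issued (the attribution stage must then drop the DTW term).
    """
    water = np.asarray(water_mask, dtype=bool)
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    labels, n = ndimage.label(water, structure=structure)
    if n:
        counts = np.bincount(labels.ravel())[1:]
        areas = counts * cell_size**2
        keep = np.flatnonzero(areas > min_area_m2) + 1
        qualifying = np.isin(labels, keep)
    else:
        qualifying = np.zeros_like(water)
    if not qualifying.any():
        warnings.warn("no qualifying bluespace in scene; DTW is +inf", stacklevel=2)
        return np.full(water.shape, np.inf)
    dist = ndimage.distance_transform_edt(~qualifying, sampling=cell_size)
    return dist / 1000.0
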
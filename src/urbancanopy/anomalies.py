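"""Spatial anomalies of canopy temperature.

A single scalar reference — the land-only domain-mean LST of the overpass —
is subtracted from the canopy temperature map, yielding ΔLST_canopy.  Using
a per-image spatial reference removes day-to-day weather offsets when
overpasses from different days are compared as a pseudo-diurnal cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import LSTRaster

__all__ = ["AnomalyRaster", "domain_mean", "anomaly_map"]


@dataclass
class AnomalyRaster:
    """ΔLST field (K) with its scalar reference and overpass time."""

    delta: np.ndarray
    reference_mean: float
    overpass_local_time: float


def domain_mean(lst: LSTRaster, land_mask: np.ndarray) -> float:
    """Arithmetic mean LST over land pixels (water and nodata excluded)."""
    sel = np.asarray(land_mask, bool) & ~lst.nodata_mask
    if not sel.any():
        raise ValueError("empty land mask: no pixels to average")
    return float(lst.lst[sel].mean())


def anomaly_map(canopy: np.ndarray, ref_mean: float,
                overpass_local_time: float = np.nan) -> AnomalyRaster:
    """Per-pixel subtraction of the scalar reference; NaN propagates."""
    return AnomalyRaster(
        delta=np.asarray(canopy, float) - ref_mean,
        reference_mean=float(ref_mean),
        overpass_local_time=overpass_local_time,
    )
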
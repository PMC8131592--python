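"""Diurnal and zonal summaries of canopy temperature anomalies.

Per-overpass spatial statistics of ΔLST_canopy, pixel-level contrasts of
each surface class against the tree canopy, zonal (borough-analogue) means,
and assembly of the pseudo-diurnal table across overpasses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .anomalies import AnomalyRaster
from .classes import N_CLASSES, SURFACE_CLASSES, TREE
from .decompose import ElementTemperatureStack

__all__ = [
    "spatial_stats",
    "element_contrast",
    "zonal_mean",
    "build_diurnal_table",
]


def spatial_stats(delta: AnomalyRaster) -> tuple[float, float, int]:
    """Spatial mean and population STD of the anomaly over valid pixels."""
    vals = delta.delta[np.isfinite(delta.delta)]
    if vals.size < 2:
        raise ValueError("need at least 2 valid anomaly pixels")
    return float(vals.mean()), float(vals.std(ddof=0)), int(vals.size)


def element_contrast(stack: ElementTemperatureStack) -> pd.DataFrame:
    """Pixelwise contrast of each non-tree class against the tree canopy.

    Positive mean = element warmer than canopy.  A pixel counts for a class
    only when both that class and the tree class are solved there.
    """
    tree = stack.temps[TREE]
    rows = []
    for k in range(N_CLASSES):
        if k == TREE:
            continue
        both = stack.solved_mask[k] & stack.solved_mask[TREE]
        if not both.any():
            warnings.warn(
                f"no co-solved pixels for class {SURFACE_CLASSES[k]}", stacklevel=2
            )
            rows.append({"element": SURFACE_CLASSES[k], "mean_k": np.nan,
                         "std_k": np.nan, "n": 0})
            continue
        diff = stack.temps[k][both] - tree[both]
        rows.append({
            "element": SURFACE_CLASSES[k],
            "mean_k": float(diff.mean()),
            "std_k": float(diff.std(ddof=0)),
            "n": int(diff.size),
        })
    return pd.DataFrame(rows).set_index("element")


def zonal_mean(delta: AnomalyRaster, zone_id: np.ndarray) -> pd.Series:
    """NaN-aware mean anomaly per zone label."""
    d = delta.delta.ravel()
    z = np.asarray(zone_id).ravel()
    ok = np.isfinite(d)
    df = pd.DataFrame({"zone": z[ok], "delta": d[ok]})
    return df.groupby("zone")["delta"].mean()


def build_diurnal_table(
    products: list[tuple[float, AnomalyRaster, ElementTemperatureStack]],
    sunrise: float,
    sunset: float,
) -> pd.DataFrame:
    """Assemble the diurnal summary table.

    One row per overpass (sorted by local time): spatial mean/STD of the
    anomaly, day/night label from the sunrise/sunset metadata, and the
    per-element canopy contrasts.  Duplicate times are kept with a warning.
    """
    if len(products) < 2:
        raise ValueError("need at least 2 overpasses for a diurnal table")
    times = [t for t, _, _ in products]
    if len(set(times)) != len(times):
        warnings.warn("duplicate overpass times; keeping all rows", stacklevel=2)
    rows = []
    for t, delta, stack in sorted(products, key=lambda p: p[0]):
        mean, std, n = spatial_stats(delta)
        row: dict = {
            "local_time": t,
            "day_night": "day" if sunrise < t < sunset else "night",
            "spatial_mean_delta_k": mean,
            "spatial_std_delta_k": std,
            "n_pixels": n,
        }
        contrast = element_contrast(stack)
        for name, rec in contrast.iterrows():
            row[f"contrast_mean_{name}_k"] = rec["mean_k"]
            row[f"contrast_std_{name}_k"] = rec["std_k"]
        rows.append(row)
    return pd.DataFrame(rows)
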
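"""Attribution of canopy-anomaly spatial variation with penalized-spline GAMs.

At the 350-m neighborhood scale (5×5 thermal pixels) the anomaly is modeled
as a sum of smooth functions of green-area fraction (GAF), distance to
bluespace (DTW), and area-weighted building height (BH), tensor-product
interactions ti(GAF,DTW) and ti(DTW,BH), and a low-rank spatial smooth:

    Δ ~ s(gaf, k=6) + s(dtw, k=6) + s(bh, k=3) + ti(gaf,dtw) + ti(dtw,bh)
        + s(x, y, k=10 city / k=2 zone)

Basis dimensions are deliberately small so each curve captures the
city-scale trend, not local texture.  Smoothing parameters are selected by
REML.  Fitting is delegated to mgcv (run through Rscript); the neighborhood
table, fitted curves, and maximum-temperature-effect (MTE) extraction live
here.  Each overpass is fitted independently.

The MTE of a covariate is the max-minus-min of the model prediction over a
stated covariate range with the other covariates held at their medians and
the spatial smooth at the domain centroid.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .anomalies import AnomalyRaster
from .raster import CovariateGrids
from .georef import GridGeoref

__all__ = [
    "NeighborhoodTable",
    "GAMResult",
    "MTEResult",
    "build_table",
    "fit_attribution",
    "compute_mte",
    "effect_share",
]


@dataclass
class GAMResult:
    """Fitted attribution model: curves, term table, and diagnostics."""

    n: int
    deviance_explained: float
    smooth_table: pd.DataFrame  # term, edf, statistic, p_value
    curves: pd.DataFrame  # variable, value, pred, pred_se, term_fit, term_se
    terms_at_data: pd.DataFrame
    medians: dict[str, float]
    support: dict[str, tuple[float, float]]
    dropped_terms: tuple[str, ...]
    scale: str
    formula: str

    def partial_effect(self, variable: str) -> pd.DataFrame:
        """Centered partial-effect curve (value, term_fit, 95% CI bounds)."""
        c = self.curves[self.curves["variable"] == variable].copy()
        if c.empty:
            raise KeyError(f"no fitted smooth for {variable!r}")
        c["ci_lo"] = c["term_fit"] - 1.96 * c["term_se"]
        c["ci_hi"] = c["term_fit"] + 1.96 * c["term_se"]
        return c.reset_index(drop=True)

    def p_value(self, variable: str) -> float:
        row = self.smooth_table[self.smooth_table["term"] == f"s({variable})"]
        return float(row["p_value"].iloc[0]) if len(row) else np.nan


@dataclass
class MTEResult:
    """Maximum temperature effect of one covariate over a range."""

    variable: str
    eval_range: tuple[float, float]
    mte: float
    significant: bool


NeighborhoodTable = pd.DataFrame  # columns: delta, gaf, dtw, bh, x, y, zone


def build_table(
    delta: AnomalyRaster,
    covariates: CovariateGrids,
    block: int = 5,
    georef: GridGeoref | None = None,
) -> pd.DataFrame:
    """Aggregate pixel grids to block×block neighborhood records.

    delta and GAF/BH are block means (delta NaN-aware over valid canopy
    pixels), DTW is taken at the block-center pixel, zone is the block-center
    zone id, and (x, y) are block-center coordinates in km.  Cells with no
    valid canopy pixel are dropped.
    """
    d = delta.delta
    if d.shape != covariates.gaf.shape:
        raise ValueError("anomaly and covariate grids must share a shape")
    rows, cols = d.shape
    nr, nc = rows // block, cols // block
    if nr == 0 or nc == 0:
        raise ValueError("raster smaller than one neighborhood block")
    cell_km = (georef.cell if georef else 70.0) / 1000.0

    def blocks(a: np.ndarray) -> np.ndarray:
        return a[: nr * block, : nc * block].reshape(nr, block, nc, block)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        dmean = np.nanmean(blocks(d), axis=(1, 3))
    gaf = blocks(covariates.gaf).mean(axis=(1, 3))
    bh = blocks(covariates.bh).mean(axis=(1, 3))
    c = block // 2
    dtw = blocks(covariates.dtw)[:, c, :, c]
    zone = blocks(covariates.zone_id)[:, c, :, c]
    bi, bj = np.mgrid[0:nr, 0:nc]
    x = (bj * block + block / 2.0) * cell_km
    y = ((rows - bi * block) - block / 2.0) * cell_km

    table = pd.DataFrame({
        "delta": dmean.ravel(), "gaf": gaf.ravel(), "dtw": dtw.ravel(),
        "bh": bh.ravel(), "x": x.ravel(), "y": y.ravel(),
        "zone": zone.ravel().astype(int),
    })
    n_dropped = int(table["delta"].isna().sum())
    table = table.dropna(subset=["delta"]).reset_index(drop=True)
    table.attrs["n_dropped"] = n_dropped
    return table


def _build_formula(table: pd.DataFrame, scale: str,
                   spatial: bool = True) -> tuple[str, tuple[str, ...]]:
    """Assemble the mgcv formula, dropping unusable terms."""
    k_xy = 10 if scale == "city" else 2
    dropped: list[str] = []
    use = {}
    for v, k in (("gaf", 6), ("dtw", 6), ("bh", 3)):
        vals = table[v]
        if not np.all(np.isfinite(vals)) or vals.nunique() < 3:
            dropped.append(v)
            warnings.warn(f"dropping constant/degenerate term s({v})", stacklevel=3)
        else:
            use[v] = k
    terms = [f"s({v},k={k})" for v, k in use.items()]
    if "gaf" in use and "dtw" in use:
        terms.append("ti(gaf,dtw)")
    if "dtw" in use and "bh" in use:
        terms.append("ti(dtw,bh)")
    if spatial:
        terms.append(f"s(x,y,k={k_xy})")
    return "delta ~ " + " + ".join(terms), tuple(dropped)


def fit_attribution(table: pd.DataFrame, scale: str = "city",
                    spatial: bool = True) -> GAMResult:
    """Fit the attribution GAM for one overpass via the mgcv backend.

    ``scale`` selects the spatial-smooth basis dimension: "city" (k=10) or
    "zone" (k=2, a nearly planar surface for borough-sized subsets).  Tables
    with fewer than ~200 rows trigger a warning (basis reduction is left to
    the backend, which caps k at the data's support).
    """
    if scale not in ("city", "zone"):
        raise ValueError("scale must be 'city' or 'zone'")
    required = {"delta", "gaf", "dtw", "bh", "x", "y"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    if len(table) < 200:
        warnings.warn(
            f"only {len(table)} neighborhoods; smooth estimates may be unstable",
            stacklevel=2,
        )
    formula, dropped = _build_formula(table, scale, spatial)
    rscript = shutil.which("Rscript")
    if rscript is None:
        raise RuntimeError("Rscript not found; the GAM backend requires R + mgcv")
    script = resources.files("urbancanopy") / "r" / "fit_gam.R"

    with tempfile.TemporaryDirectory(prefix="urbancanopy_gam_") as tmp:
        tmpdir = Path(tmp)
        data_path = tmpdir / "table.csv"
        cols = ["delta", "gaf", "dtw", "bh", "x", "y"]
        table[cols].to_csv(data_path, index=False)
        with resources.as_file(script) as script_path:
            proc = subprocess.run(
                [rscript, "--vanilla", str(script_path), str(data_path),
                 str(tmpdir), formula],
                capture_output=True, text=True,
            )
        if proc.returncode != 0:
            raise RuntimeError(f"mgcv backend failed:\n{proc.stderr}")
        summary = json.loads((tmpdir / "summary.json").read_text())
        curves = pd.read_csv(tmpdir / "curves.csv")
        terms_at_data = pd.read_csv(tmpdir / "terms_at_data.csv")

    smooth_table = pd.DataFrame(summary["terms"])
    medians = {v: float(table[v].median()) for v in ("gaf", "dtw", "bh")
               if v not in dropped}
    support = {v: (float(table[v].min()), float(table[v].max()))
               for v in ("gaf", "dtw", "bh") if v not in dropped}
    return GAMResult(
        n=int(summary["n"]),
        deviance_explained=float(summary["deviance_explained"]),
        smooth_table=smooth_table,
        curves=curves,
        terms_at_data=terms_at_data,
        medians=medians,
        support=support,
        dropped_terms=dropped,
        scale=scale,
        formula=formula,
    )


def compute_mte(
    result: GAMResult,
    variable: str,
    eval_range: tuple[float, float] | None = None,
) -> MTEResult:
    """Maximum temperature effect: max − min predicted anomaly over a range.

    Predictions hold the other covariates at their medians and the spatial
    smooth at the domain centroid (precomputed on a dense grid at fit time;
    evaluated here on a 200-point grid by interpolation).  A requested range
    outside the data support is clipped with a warning.  A dropped term has
    MTE 0.
    """
    if variable in result.dropped_terms:
        return MTEResult(variable, (0.0, 0.0), 0.0, False)
    curve = result.curves[result.curves["variable"] == variable]
    if curve.empty:
        raise KeyError(f"variable {variable!r} has no fitted smooth")
    lo_s, hi_s = result.support[variable]
    if eval_range is None:
        eval_range = (lo_s, hi_s)
    lo, hi = eval_range
    if lo < lo_s - 1e-12 or hi > hi_s + 1e-12:
        warnings.warn(
            f"range {eval_range} outside data support ({lo_s:.3g}, {hi_s:.3g}); "
            "clipping", stacklevel=2,
        )
        lo, hi = max(lo, lo_s), min(hi, hi_s)
    grid = np.linspace(lo, hi, 200)
    pred = np.interp(grid, curve["value"].to_numpy(), curve["pred"].to_numpy())
    mte = float(pred.max() - pred.min())
    p = result.p_value(variable)
    return MTEResult(variable, (float(lo), float(hi)), mte,
                     bool(np.isfinite(p) and p < 0.05))


def effect_share(mtes: list[MTEResult]) -> dict[str, float]:
    """Relative share (%) of each covariate's MTE in the summed MTE.

    The decomposition is an interpretation — MTEs are range sensitivities,
    not orthogonal variance components — but gives a simple ranking of
    factor importance.  Shares sum to 100.
    """
    if len(mtes) < 2:
        raise ValueError("need at least two MTEs to form shares")
    total = sum(m.mte for m in mtes)
    if total <= 0:
        raise ValueError("all MTEs are zero; shares undefined")
    return {m.variable: 100.0 * m.mte / total for m in mtes}
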
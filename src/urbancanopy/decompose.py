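"""Sub-pixel element temperature retrieval by bounded least squares in T⁴.

The mixing model treats each thermal pixel's emissivity-weighted radiance as
an area-weighted sum over the 8 surface classes:

    ε(i,j) · LST(i,j)⁴ = Σₖ εₖ · fₖ(i,j) · Tₖ(i,j)⁴ + r(i,j)

Within a small moving window the element temperatures are assumed shared, so
stacking the window's pixels gives a linear system in the unknowns xₖ = Tₖ⁴
with design A[p,k] = εₖ·fₖ(p) and target y[p] = ε(p)·LST(p)⁴.  The system is
solved by bounded linear least squares (trust-region-reflective) with box
constraints t_min⁴ ≤ xₖ ≤ t_max⁴ derived from the domain's observed LST
range, which regularizes weakly determined classes.  Classes whose summed
fraction over the window is negligible are unidentifiable and dropped.

The solver first tries the unconstrained least-squares solution (exact for
this convex problem) and falls back to the trust-region-reflective bounded
solver only when a bound is violated, which keeps full-image sweeps fast
without changing the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .classes import N_CLASSES, SURFACE_CLASSES, TREE
from .raster import FractionStack, LSTRaster

__all__ = [
    "SolveBounds",
    "ElementTemperatureStack",
    "decompose_window",
    "decompose_image",
    "kernel_sensitivity",
    "canopy_map",
    "FLAG_LOW_FRACTION_DROP",
    "FLAG_RANK_DEFICIENT",
    "FLAG_BOUND_ACTIVE",
    "FLAG_UNSOLVED",
]

# condition_flag bit codes
FLAG_LOW_FRACTION_DROP = 1
FLAG_RANK_DEFICIENT = 2
FLAG_BOUND_ACTIVE = 4
FLAG_UNSOLVED = 8

MIN_WINDOW_PIXELS = 8


@dataclass(frozen=True)
class SolveBounds:
    """Box constraints on solved element temperatures (K)."""

    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError("t_min must be < t_max")
        if self.t_min <= 0:
            raise ValueError("temperatures are absolute; t_min must be positive")


@dataclass
class ElementTemperatureStack:
    """Solved per-class temperatures and solve diagnostics.

    temps is (8, rows, cols) in K with NaN where a class was not solved;
    residual_rms is the window residual RMS in T⁴ units (K⁴) and residual_k
    its linearized Kelvin equivalent; condition_flag is a per-pixel bitmask
    (low-fraction class drops / rank deficiency / active bounds / unsolved).
    """

    temps: np.ndarray
    residual_rms: np.ndarray
    residual_k: np.ndarray
    solved_mask: np.ndarray
    condition_flag: np.ndarray
    bounds: SolveBounds
    kernel: int


def _solve_active(A: np.ndarray, y: np.ndarray, lo: float, hi: float,
                  scale: float) -> tuple[np.ndarray, int, bool]:
    """Solve min‖Ax−y‖² s.t. lo ≤ x ≤ hi (all in K⁴ units).

    Variables are scaled by ``scale`` (t_max⁴) for conditioning.  Returns
    (x, rank, bound_active).  The unconstrained solution is accepted when it
    is feasible; otherwise the bounded trust-region-reflective solver runs.
    """
    As = A * scale
    ys = y
    x_s, _, rank, _ = np.linalg.lstsq(As, ys, rcond=None)
    lo_s, hi_s = lo / scale, hi / scale
    tol = 1e-9 * hi_s
    if rank == A.shape[1] and np.all(x_s >= lo_s - tol) and np.all(x_s <= hi_s + tol):
        return np.clip(x_s, lo_s, hi_s) * scale, rank, False
    res = lsq_linear(As, ys, bounds=(lo_s, hi_s), method="trf", tol=1e-12)
    return np.clip(res.x, lo_s, hi_s) * scale, rank, True


def decompose_window(
    lst_w: np.ndarray,
    emis_w: np.ndarray,
    fracs_w: np.ndarray,
    class_emis: np.ndarray,
    bounds: SolveBounds,
    min_fraction: float = 0.02,
) -> tuple[np.ndarray, dict]:
    """Solve one window.

    lst_w, emis_w: (n_pixels,) valid-pixel vectors; fracs_w: (8, n_pixels).
    Returns (temps[8] with NaN for unsolved classes, diagnostics dict with
    residual stats and flags).  Classes whose summed fraction over the
    window is below ``min_fraction``·n_pixels are dropped as unidentifiable;
    a rank-deficient design is repaired by iteratively dropping the class
    with the smallest summed fraction.
    """
    lst_w = np.asarray(lst_w, float).ravel()
    emis_w = np.asarray(emis_w, float).ravel()
    fracs_w = np.asarray(fracs_w, float).reshape(N_CLASSES, -1)
    n = lst_w.size
    temps = np.full(N_CLASSES, np.nan)
    diag = {
        "n_pixels": n, "flags": 0, "residual_rms": np.nan,
        "residual_mean": np.nan, "residual_k": np.nan,
        "active": np.zeros(N_CLASSES, bool),
    }
    if n < MIN_WINDOW_PIXELS:
        diag["flags"] |= FLAG_UNSOLVED
        return temps, diag

    frac_sum = fracs_w.sum(axis=1)
    present = frac_sum > 0
    active = present & (frac_sum >= min_fraction * n)
    if not active.any():
        diag["flags"] |= FLAG_UNSOLVED
        return temps, diag
    if np.any(present & ~active):  # present but too weak to identify
        diag["flags"] |= FLAG_LOW_FRACTION_DROP

    y = emis_w * lst_w**4
    scale = bounds.t_max**4
    lo, hi = bounds.t_min**4, bounds.t_max**4

    order = np.argsort(frac_sum)  # weakest first, for deterministic drops
    while True:
        idx = np.flatnonzero(active)
        A = (class_emis[idx][None, :] * fracs_w[idx].T)
        x, rank, bounded = _solve_active(A, y, lo, hi, scale)
        if rank == idx.size or idx.size == 1:
            break
        diag["flags"] |= FLAG_RANK_DEFICIENT
        for k in order:
            if active[k]:
                active[k] = False
                break
        if not active.any():
            diag["flags"] |= FLAG_UNSOLVED
            return temps, diag

    if bounded:
        diag["flags"] |= FLAG_BOUND_ACTIVE
    temps[idx] = x**0.25
    r = y - A @ x
    diag["active"] = active
    diag["residual_rms"] = float(np.sqrt(np.mean(r**2)))
    diag["residual_mean"] = float(np.mean(r))
    tbar = float(np.mean(lst_w))
    diag["residual_k"] = diag["residual_rms"] / (4.0 * tbar**3)
    return temps, diag


def decompose_image(
    lst: LSTRaster,
    fracs: FractionStack,
    class_emis: np.ndarray | None = None,
    bounds: SolveBounds | None = None,
    kernel: int = 5,
    min_fraction: float = 0.02,
) -> ElementTemperatureStack:
    """Slide a kernel×kernel window over the image (stride 1) and assign each
    window's solution to its center pixel.

    Bounds default to the (min, max) of unmasked LST in the image — the
    domain-wide constrained rule.  Border windows shrink to the valid
    overlap and are solved when at least 8 usable pixels remain.
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    valid = ~lst.nodata_mask
    if not valid.any():
        raise ValueError("fully masked image")
    if class_emis is None:
        from .classes import DEFAULT_EMISSIVITY
        class_emis = DEFAULT_EMISSIVITY
    class_emis = np.asarray(class_emis, float)
    if bounds is None:
        vals = lst.lst[valid]
        bounds = SolveBounds(float(vals.min()), float(vals.max()))

    rows, cols = lst.shape
    h = kernel // 2
    f = fracs.fractions
    temps = np.full((N_CLASSES, rows, cols), np.nan)
    residual_rms = np.full((rows, cols), np.nan)
    residual_k = np.full((rows, cols), np.nan)
    flags = np.zeros((rows, cols), dtype=np.int8)

    lstv = lst.lst
    emisv = lst.emissivity
    for i in range(rows):
        r0, r1 = max(0, i - h), min(rows, i + h + 1)
        for j in range(cols):
            c0, c1 = max(0, j - h), min(cols, j + h + 1)
            m = valid[r0:r1, c0:c1].ravel()
            if m.sum() < MIN_WINDOW_PIXELS:
                flags[i, j] = FLAG_UNSOLVED
                continue
            lw = lstv[r0:r1, c0:c1].ravel()[m]
            ew = emisv[r0:r1, c0:c1].ravel()[m]
            fw = f[:, r0:r1, c0:c1].reshape(N_CLASSES, -1)[:, m]
            t, d = decompose_window(lw, ew, fw, class_emis, bounds, min_fraction)
            temps[:, i, j] = t
            residual_rms[i, j] = d["residual_rms"]
            residual_k[i, j] = d["residual_k"]
            flags[i, j] = d["flags"]

    solved = ~np.isnan(temps)
    return ElementTemperatureStack(
        temps=temps, residual_rms=residual_rms, residual_k=residual_k,
        solved_mask=solved, condition_flag=flags, bounds=bounds, kernel=kernel,
    )


def canopy_map(
    stack: ElementTemperatureStack,
    fracs: FractionStack,
    canopy_fraction_min: float = 0.05,
) -> np.ndarray:
    """Tree-canopy temperature raster: the tree-class solution where the
    pixel's own tree fraction is at least ``canopy_fraction_min``, else NaN."""
    out = stack.temps[TREE].copy()
    out[fracs.fractions[TREE] < canopy_fraction_min] = np.nan
    return out


def kernel_sensitivity(
    lst: LSTRaster,
    fracs: FractionStack,
    true_temps: np.ndarray,
    class_emis: np.ndarray | None = None,
    bounds: SolveBounds | None = None,
    kernels: tuple[int, ...] = (3, 5, 7, 9),
    min_window_fraction: float = 0.1,
    eval_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score window sizes against known truth.

    For each kernel: decompose, then per-class RMSE vs truth over cleanly
    solved pixels (no identifiability drops or active bounds) where the
    class's own fraction ≥ ``min_window_fraction`` (weakly present classes
    are not informative), mean Kelvin-equivalent residual, and the number of
    solved windows as a runtime proxy.  ``eval_mask`` optionally restricts
    scoring to chosen pixels (e.g. tile centers of a tiled-truth scene).
    """
    rows = []
    for k in kernels:
        stack = decompose_image(lst, fracs, class_emis, bounds, kernel=k)
        rec: dict = {"kernel": k}
        errs = []
        clean = stack.condition_flag == 0
        if eval_mask is not None:
            clean = clean & eval_mask
        for c, name in enumerate(SURFACE_CLASSES):
            sel = clean & stack.solved_mask[c] \
                & (fracs.fractions[c] >= min_window_fraction)
            if sel.any():
                e = stack.temps[c][sel] - true_temps[c][sel]
                rec[f"rmse_{name}"] = float(np.sqrt(np.mean(e**2)))
                errs.append(e)
            else:
                rec[f"rmse_{name}"] = np.nan
        rec["rmse_overall"] = float(
            np.sqrt(np.mean(np.concatenate(errs) ** 2))) if errs else np.nan
        rec["mean_residual_k"] = float(np.nanmean(stack.residual_k))
        rec["n_solves"] = int(np.sum((stack.condition_flag & FLAG_UNSOLVED) == 0))
        rows.append(rec)
    return pd.DataFrame(rows)
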
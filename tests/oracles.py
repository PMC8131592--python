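"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most transparent method available
(exhaustive enumeration, direct summation, dense grid search) and is kept
free of any code path it is used to check.
"""

from __future__ import annotations

import numpy as np


def brute_force_distance_km(water_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """O(N·W) distance to the nearest water-cell center, in km.

    No component-area filtering: apply that to the mask before calling.
    """
    water = np.argwhere(water_mask)
    rows, cols = water_mask.shape
    out = np.full((rows, cols), np.inf)
    if water.size == 0:
        return out
    for i in range(rows):
        for j in range(cols):
            d2 = ((water[:, 0] - i) ** 2 + (water[:, 1] - j) ** 2).min()
            out[i, j] = np.sqrt(d2) * cell_size / 1000.0
    return out


def grid_search_temperatures(
    lst_w: np.ndarray,
    emis_w: np.ndarray,
    fracs_w: np.ndarray,
    class_emis: np.ndarray,
    active: np.ndarray,
    t_min: float,
    t_max: float,
    final_step: float = 0.01,
) -> np.ndarray:
    """Exhaustive grid search over element temperatures for ≤3 active classes.

    Minimizes the sum of squared residuals of the emissivity-weighted T⁴
    mixing relation on a temperature grid refined from 1 K down to
    ``final_step`` K.  The objective is convex in T⁴ (hence unimodal along
    the refinement path), so coarse-to-fine exhaustive search reaches the
    global bounded optimum.
    """
    idx = np.flatnonzero(active)
    if idx.size > 3:
        raise ValueError("grid search supports at most 3 active classes")
    A = class_emis[idx][None, :] * fracs_w[idx].T  # (n_pix, n_active)
    y = emis_w * lst_w**4

    lo = np.full(idx.size, t_min)
    hi = np.full(idx.size, t_max)
    best = None
    step = 1.0
    while True:
        axes = [np.arange(lo[a], hi[a] + step / 2, step) for a in range(idx.size)]
        grids = np.meshgrid(*axes, indexing="ij")
        T = np.stack([g.ravel() for g in grids], axis=1)  # (n_comb, n_active)
        resid = A @ (T**4).T - y[:, None]
        sse = np.einsum("pc,pc->c", resid, resid)
        k = int(np.argmin(sse))
        best = T[k]
        if step <= final_step:
            break
        lo = np.maximum(best - step, t_min)
        hi = np.minimum(best + step, t_max)
        step /= 10.0
    return best, idx


def two_pass_std(values: np.ndarray) -> float:
    """Population standard deviation by the explicit two-pass formula."""
    v = np.asarray(values, float).ravel()
    m = v.sum() / v.size
    return float(np.sqrt(((v - m) ** 2).sum() / v.size))
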
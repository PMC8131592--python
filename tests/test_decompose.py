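"""Bounded least-squares unmixing of element temperatures."""

import numpy as np
import pytest

import urbancanopy as uc
from urbancanopy.decompose import (
    FLAG_BOUND_ACTIVE,
    FLAG_UNSOLVED,
    decompose_window,
)

from .oracles import grid_search_temperatures

EPS8 = uc.DEFAULT_EMISSIVITY
BOUNDS = uc.SolveBounds(280.0, 320.0)


def _compose_window(fracs_w, temps8, class_emis):
    """Noise-free window observables from the mixing relation."""
    eps_pix = class_emis @ fracs_w
    rad = (class_emis * temps8**4) @ fracs_w
    return (rad / eps_pix) ** 0.25, eps_pix


class TestDecomposeWindow:
    def test_pure_class_identity(self):
        n = 25
        fracs = np.zeros((uc.N_CLASSES, n))
        fracs[uc.CLASS_INDEX["tree_canopy"]] = 1.0
        temps, diag = decompose_window(
            np.full(n, 300.0), np.ones(n), fracs, np.ones(uc.N_CLASSES), BOUNDS
        )
        assert temps[uc.CLASS_INDEX["tree_canopy"]] == pytest.approx(300.0, abs=1e-9)
        assert np.isnan(np.delete(temps, uc.CLASS_INDEX["tree_canopy"])).all()
        assert diag["residual_rms"] == pytest.approx(0.0, abs=1e-3)

    def test_two_class_noise_free_recovery(self):
        truth = np.full(uc.N_CLASSES, np.nan)
        truth[0], truth[5] = 295.0, 310.0
        fracs = np.zeros((uc.N_CLASSES, 25))
        fracs[0] = np.linspace(0.2, 0.8, 25)
        fracs[5] = 1.0 - fracs[0]
        t8 = np.where(np.isnan(truth), 300.0, truth)
        lst_w, eps_pix = _compose_window(fracs, t8, EPS8)
        temps, diag = decompose_window(lst_w, eps_pix, fracs, EPS8, BOUNDS)
        assert temps[0] == pytest.approx(295.0, abs=1e-3)
        assert temps[5] == pytest.approx(310.0, abs=1e-3)
        # independent dense grid-search oracle agrees
        best, idx = grid_search_temperatures(
            lst_w, eps_pix, fracs, EPS8, ~np.isnan(truth), 280.0, 320.0
        )
        np.testing.assert_allclose(temps[idx], best, atol=0.02)

    def test_truth_beyond_upper_bound_clips_exactly(self):
        truth8 = np.full(uc.N_CLASSES, 300.0)
        truth8[5] = BOUNDS.t_max + 5.0
        fracs = np.zeros((uc.N_CLASSES, 25))
        fracs[0] = np.linspace(0.3, 0.7, 25)
        fracs[5] = 1.0 - fracs[0]
        lst_w, eps_pix = _compose_window(fracs, truth8, EPS8)
        temps, diag = decompose_window(lst_w, eps_pix, fracs, EPS8, BOUNDS)
        assert temps[5] == pytest.approx(BOUNDS.t_max, abs=1e-9)
        assert diag["flags"] & FLAG_BOUND_ACTIVE

    def test_too_few_pixels_flagged_unsolved(self):
        fracs = np.zeros((uc.N_CLASSES, 5))
        fracs[0] = 1.0
        temps, diag = decompose_window(
            np.full(5, 300.0), np.ones(5), fracs, np.ones(uc.N_CLASSES), BOUNDS
        )
        assert diag["flags"] & FLAG_UNSOLVED
        assert np.isnan(temps).all()


class TestDecomposeImage:
    def test_constant_scene_recovers_pixel_lst(self, rng):
        shape = (20, 20)
        f = rng.dirichlet(np.ones(4), size=shape).transpose(2, 0, 1)
        fracs = np.zeros((uc.N_CLASSES,) + shape)
        fracs[:4] = f
        fs = uc.FractionStack(fracs, uc.GridGeoref(0, 0, 70.0))
        temps_true = np.full((uc.N_CLASSES,) + shape, 300.0)
        lst = uc.forward_compose(temps_true, fs, EPS8, 0.0, 0)
        stack = uc.decompose_image(lst, fs, EPS8, bounds=BOUNDS)
        clean = stack.condition_flag == 0
        sel = stack.solved_mask & clean[None]
        np.testing.assert_allclose(stack.temps[sel], 300.0, atol=1e-6)

    def test_solutions_respect_bounds(self, decomposed_midday):
        *_, stack = decomposed_midday
        solved = stack.temps[stack.solved_mask]
        assert solved.min() >= stack.bounds.t_min - 1e-9
        assert solved.max() <= stack.bounds.t_max + 1e-9

    def test_residual_orthogonality_on_clean_windows(self, decomposed_midday):
        # interior optimum => normal equations hold: A^T (y - A x) = 0, which
        # implies the window-mean radiance budget closes
        cfg, truth, fractions, lst, stack = decomposed_midday
        eps = cfg.class_emissivities
        rows, cols = lst.shape
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 25:
            i = int(rng.integers(2, rows - 2))
            j = int(rng.integers(2, cols - 2))
            if stack.condition_flag[i, j] != 0:
                continue
            fw = fractions.fractions[:, i-2:i+3, j-2:j+3].reshape(uc.N_CLASSES, -1)
            lw = lst.lst[i-2:i+3, j-2:j+3].ravel()
            ew = lst.emissivity[i-2:i+3, j-2:j+3].ravel()
            active = ~np.isnan(stack.temps[:, i, j])
            A = (eps[active][None, :] * fw[active].T)
            y = ew * lw**4
            r = y - A @ stack.temps[active, i, j] ** 4
            scale = np.linalg.norm(A, axis=0) * np.linalg.norm(y)
            assert np.all(np.abs(A.T @ r) <= 1e-7 * scale)
            checked += 1

    def test_even_or_tiny_kernel_rejected(self, decomposed_midday):
        cfg, truth, fractions, lst, _ = decomposed_midday
        with pytest.raises(ValueError):
            uc.decompose_image(lst, fractions, kernel=4)
        with pytest.raises(ValueError):
            uc.decompose_image(lst, fractions, kernel=1)

    def test_rmse_nondecreasing_in_noise(self):
        from scipy.ndimage import uniform_filter
        rmses = []
        for sigma in (0.0, 0.25, 0.5):
            errs = []
            for seed in (3, 11):
                cfg = uc.SceneConfig(grid_rows=40, grid_cols=40, seed=seed,
                                     overpass_times=(13.0,), noise_sigma=sigma)
                truth, fs, _, ops = uc.build_scene_products(cfg)
                stack = uc.decompose_image(ops[0], fs, cfg.class_emissivities)
                tt = truth.true_element_temps[13.0]
                for k in range(uc.N_CLASSES):
                    wf = uniform_filter(fs.fractions[k], 5)
                    sel = stack.solved_mask[k] & (wf >= 0.1)
                    if sel.any():
                        errs.append(stack.temps[k][sel] - tt[k][sel])
            rmses.append(float(np.sqrt(np.mean(np.concatenate(errs) ** 2))))
        assert rmses[0] <= rmses[1] + 0.05
        assert rmses[1] <= rmses[2] + 0.05


class TestKernelSensitivity:
    def test_tile3_truth_prefers_kernel3(self):
        cfg = uc.SceneConfig(grid_rows=30, grid_cols=30, seed=9,
                             overpass_times=(13.0,), noise_sigma=0.0,
                             truth_tile=3)
        truth, fs, _, ops = uc.build_scene_products(cfg)
        tt = truth.true_element_temps[13.0]
        bounds = uc.SolveBounds(float(tt.min()) - 2, float(tt.max()) + 2)
        # score at tile centers, where a 3x3 window matches a tile exactly
        centers = np.zeros((30, 30), bool)
        centers[1::3, 1::3] = True
        table = uc.kernel_sensitivity(ops[0], fs, tt, cfg.class_emissivities,
                                      bounds, kernels=(3, 5, 7),
                                      eval_mask=centers)
        assert table.loc[table["kernel"] == 3, "rmse_overall"].iloc[0] == \
            table["rmse_overall"].min()

    def test_constant_truth_all_kernels_near_zero(self):
        cfg = uc.SceneConfig(grid_rows=30, grid_cols=30, seed=9,
                             overpass_times=(13.0,), noise_sigma=0.0,
                             texture_sigma=0.0, gaf_slope=0, dtw_amplitude=0,
                             bh_day_coeff=0, bh_night_coeff=0)
        truth, fs, _, ops = uc.build_scene_products(cfg)
        tt = truth.true_element_temps[13.0]
        bounds = uc.SolveBounds(float(tt.min()) - 2, float(tt.max()) + 2)
        table = uc.kernel_sensitivity(ops[0], fs, tt, cfg.class_emissivities,
                                      bounds, kernels=(3, 5, 7))
        assert (table["rmse_overall"] < 0.05).all()
        assert len(table) == 3


class TestCanopyMap:
    def test_masking_rules(self, decomposed_midday):
        cfg, truth, fractions, lst, stack = decomposed_midday
        tree = uc.CLASS_INDEX["tree_canopy"]
        canopy = uc.canopy_map(stack, fractions, canopy_fraction_min=0.05)
        no_tree = fractions.fractions[tree] == 0.0
        assert np.isnan(canopy[no_tree]).all()
        pure = (fractions.fractions[tree] >= 0.99) & stack.solved_mask[tree]
        np.testing.assert_array_equal(canopy[pure], stack.temps[tree][pure])

    def test_stricter_threshold_keeps_fewer_pixels(self, decomposed_midday):
        cfg, truth, fractions, lst, stack = decomposed_midday
        n_loose = np.isfinite(uc.canopy_map(stack, fractions, 0.05)).sum()
        n_strict = np.isfinite(uc.canopy_map(stack, fractions, 0.20)).sum()
        assert n_strict <= n_loose
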
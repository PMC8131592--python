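"""GAM attribution: neighborhood aggregation, smooth recovery, MTE extraction."""

import numpy as np
import pandas as pd
import pytest

import urbancanopy as uc


def _random_table(rng, n=400, delta=None):
    t = pd.DataFrame({
        "gaf": rng.random(n),
        "dtw": rng.random(n) * 3.0,
        "bh": rng.random(n) * 50.0,
        "x": rng.random(n) * 10.0,
        "y": rng.random(n) * 10.0,
        "zone": rng.integers(0, 6, n),
    })
    t["delta"] = rng.normal(0, 0.5, n) if delta is None else delta(t)
    return t


class TestBuildTable:
    def _grids(self, shape, rng=None):
        g = np.full(shape, 0.4) if rng is None else rng.random(shape)
        cov = uc.CovariateGrids(gaf=g, dtw=np.full(shape, 1.0),
                                bh=np.full(shape, 12.0),
                                zone_id=np.zeros(shape, int))
        return cov

    def test_constant_inputs_give_single_valued_table(self):
        shape = (10, 10)
        delta = uc.AnomalyRaster(np.full(shape, -1.5), 300.0, 13.0)
        table = uc.build_table(delta, self._grids(shape), block=5)
        assert len(table) == 4
        assert (table["delta"] == -1.5).all()
        assert (table["gaf"] == 0.4).all()

    def test_block_count_upper_bound(self):
        shape = (10, 10)
        d = np.full(shape, np.nan)
        d[:5, :5] = 1.0  # only one block has valid canopy pixels
        table = uc.build_table(uc.AnomalyRaster(d, 300.0, 13.0),
                               self._grids(shape), block=5)
        assert len(table) <= 4
        assert len(table) == 1

    def test_block_mean_matches_brute_force(self, rng):
        shape = (10, 10)
        d = rng.normal(0, 1, shape)
        d[rng.random(shape) < 0.3] = np.nan
        cov = self._grids(shape, rng)
        table = uc.build_table(uc.AnomalyRaster(d, 300.0, 13.0), cov, block=5)
        blk = d[:5, :5]
        expected = np.nanmean(blk)
        got = table.iloc[0]["delta"] if not np.isnan(expected) else None
        assert got == pytest.approx(expected, abs=1e-12)
        assert table.iloc[0]["gaf"] == pytest.approx(cov.gaf[:5, :5].mean(), abs=1e-12)

    def test_shape_mismatch_raises(self):
        delta = uc.AnomalyRaster(np.zeros((10, 10)), 300.0, 13.0)
        with pytest.raises(ValueError):
            uc.build_table(delta, self._grids((8, 8)))


class TestFitAttribution:
    def test_exact_linear_response_fits_almost_perfectly(self, rng):
        table = _random_table(rng, 500, delta=lambda t: -3.0 * t.gaf + 0.4 * t.dtw)
        res = uc.fit_attribution(table, scale="city")
        assert res.deviance_explained > 0.999

    def test_partial_effects_are_centered(self, rng):
        table = _random_table(rng, 400,
                              delta=lambda t: -2 * t.gaf + rng.normal(0, 0.3, 400))
        res = uc.fit_attribution(table)
        # main smooths carry an exact sum-to-zero identifiability constraint;
        # tensor-product interactions are only approximately centered
        for col in res.terms_at_data.columns:
            if col.startswith("s("):
                assert abs(res.terms_at_data[col].mean()) < 1e-6

    def test_known_smooth_recovered_within_ci(self, rng):
        n = 600
        f = lambda g: 2.0 * np.sin(np.pi * g)
        table = _random_table(rng, n,
                              delta=lambda t: f(t.gaf) + rng.normal(0, 0.3, n))
        res = uc.fit_attribution(table)
        curve = res.partial_effect("gaf")
        # compare on an interior 50-point grid against the centered truth
        grid = np.linspace(0.05, 0.95, 50)
        fit = np.interp(grid, curve["value"], curve["term_fit"])
        lo = np.interp(grid, curve["value"], curve["ci_lo"])
        hi = np.interp(grid, curve["value"], curve["ci_hi"])
        truth = f(grid) - np.mean(f(table["gaf"]))
        coverage = np.mean((truth >= lo) & (truth <= hi))
        assert coverage >= 0.8
        assert np.max(np.abs(fit - truth)) < 0.5

    def test_null_response_has_no_structure(self, rng):
        # pure-noise response: near-zero deviance explained and roughly
        # nominal type-I error for the main smooth terms over replicates
        pvals, dev = [], []
        for rep in range(20):
            table = _random_table(np.random.default_rng(1000 + rep), 250)
            res = uc.fit_attribution(table)
            dev.append(res.deviance_explained)
            for v in ("gaf", "dtw", "bh"):
                pvals.append(res.p_value(v))
        assert np.mean(dev) < 0.08
        assert np.mean(np.array(pvals) < 0.05) <= 0.15

    def test_spatial_smooth_never_hurts_deviance(self, rng):
        table = _random_table(rng, 400,
                              delta=lambda t: -2 * t.gaf + 0.3 * t.x
                              + rng.normal(0, 0.3, 400))
        with_xy = uc.fit_attribution(table, spatial=True)
        without_xy = uc.fit_attribution(table, spatial=False)
        assert with_xy.deviance_explained >= without_xy.deviance_explained - 1e-6

    def test_constant_covariate_term_dropped_with_warning(self, rng):
        table = _random_table(rng, 300)
        table["bh"] = 7.0
        with pytest.warns(UserWarning, match="s\\(bh\\)"):
            res = uc.fit_attribution(table)
        assert "bh" in res.dropped_terms
        assert uc.compute_mte(res, "bh").mte == 0.0

    def test_small_table_warns(self, rng):
        table = _random_table(rng, 120)
        with pytest.warns(UserWarning, match="neighborhood"):
            uc.fit_attribution(table)


class TestComputeMTE:
    @pytest.fixture(scope="class")
    def linear_fit(self):
        rng = np.random.default_rng(5)
        n = 800
        table = _random_table(rng, n,
                              delta=lambda t: -4.0 * t.gaf
                              + rng.normal(0, 0.3, n))
        return table, uc.fit_attribution(table)

    def test_linear_effect_mte(self, linear_fit):
        table, res = linear_fit
        mte = uc.compute_mte(res, "gaf", (0.0, 1.0))
        span = table["gaf"].max() - table["gaf"].min()
        assert mte.mte == pytest.approx(4.0 * span, rel=0.15)
        assert mte.significant

    def test_range_clipped_to_support_with_warning(self, linear_fit):
        _, res = linear_fit
        with pytest.warns(UserWarning, match="clip"):
            mte = uc.compute_mte(res, "gaf", (-1.0, 2.0))
        lo, hi = res.support["gaf"]
        assert mte.eval_range == (pytest.approx(lo), pytest.approx(hi))

    def test_unknown_variable_raises(self, linear_fit):
        _, res = linear_fit
        with pytest.raises(KeyError):
            uc.compute_mte(res, "elevation")


class TestEffectShare:
    def _mk(self, name, value):
        return uc.MTEResult(name, (0, 1), value, True)

    def test_simple_shares(self):
        shares = uc.effect_share(
            [self._mk("gaf", 6.0), self._mk("dtw", 3.0), self._mk("bh", 1.0)])
        assert shares == pytest.approx({"gaf": 60.0, "dtw": 30.0, "bh": 10.0})

    def test_single_dominant_factor(self):
        shares = uc.effect_share([self._mk("gaf", 5.0), self._mk("bh", 0.0)])
        assert shares["gaf"] == pytest.approx(100.0)

    def test_permutation_equivariance(self):
        a = [self._mk("gaf", 2.0), self._mk("dtw", 1.0)]
        assert uc.effect_share(a) == uc.effect_share(a[::-1])

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            uc.effect_share([self._mk("gaf", 0.0), self._mk("dtw", 0.0)])
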
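"""Screening, semivariograms, ordinary kriging and surface alignment."""

import numpy as np
import pandas as pd
import pytest

from isoassign._geo import haversine_km, pairwise_haversine_km
from isoassign.isoscape import (OrdinaryKriging, VariogramModel, align_rasters,
                                detrend, ebk_surface, empirical_variogram,
                                evaluate_trend, fit_variogram, krige_predict,
                                outlier_filter, stratified_split, Isoscape)
from isoassign.raster import Grid, Raster


def record_frame(lons, lats, values, isotope="d13C", subpop=None):
    n = len(lons)
    return pd.DataFrame({
        "id": [f"r{i}" for i in range(n)],
        "subpopulation": subpop or ["A"] * n,
        "lon": lons, "lat": lats, isotope: values,
    })


class TestOutlierFilter:
    def test_single_extreme_value_removed(self):
        df = record_frame(np.zeros(6), np.zeros(6), [10, 11, 12, 13, 14, 60])
        kept, removed = outlier_filter(df, "d13C", k=3)
        assert len(removed) == 1 and len(kept) == 5
        assert 60 not in kept["d13C"].to_numpy()

    def test_infinite_fence_removes_nothing(self):
        df = record_frame(np.zeros(6), np.zeros(6), [10, 11, 12, 13, 14, 60])
        kept, removed = outlier_filter(df, "d13C", k=np.inf)
        assert removed == [] and len(kept) == 6

    def test_zero_iqr_warns_and_keeps_all(self):
        df = record_frame(np.zeros(5), np.zeros(5), [7.0] * 5)
        with pytest.warns(UserWarning, match="zero IQR"):
            kept, removed = outlier_filter(df, "d13C")
        assert removed == [] and len(kept) == 5


class TestStratifiedSplit:
    def test_seventy_thirty_on_divisible_strata(self):
        df = record_frame(np.zeros(20), np.zeros(20), np.arange(20.0),
                          subpop=["A"] * 10 + ["B"] * 10)
        train, test = stratified_split(df, 0.7, seed=1)
        for sub in ("A", "B"):
            assert (train["subpopulation"] == sub).sum() == 7
            assert (test["subpopulation"] == sub).sum() == 3

    def test_disjoint_and_exhaustive(self):
        df = record_frame(np.zeros(23), np.zeros(23), np.arange(23.0),
                          subpop=["A"] * 11 + ["B"] * 12)
        train, test = stratified_split(df, 0.7, seed=2)
        assert set(train["id"]) | set(test["id"]) == set(df["id"])
        assert set(train["id"]) & set(test["id"]) == set()

    def test_full_train_fraction_forbidden(self):
        df = record_frame(np.zeros(4), np.zeros(4), np.arange(4.0))
        with pytest.raises(ValueError):
            stratified_split(df, 1.0)

    def test_seed_determinism(self):
        df = record_frame(np.zeros(30), np.zeros(30), np.arange(30.0),
                          subpop=["A"] * 15 + ["B"] * 15)
        t1, _ = stratified_split(df, 0.7, seed=5)
        t2, _ = stratified_split(df, 0.7, seed=5)
        t3, _ = stratified_split(df, 0.7, seed=6)
        assert list(t1["id"]) == list(t2["id"])
        assert list(t1["id"]) != list(t3["id"])
        assert len(t3) == len(t1)

    def test_tiny_stratum_rejected(self):
        df = record_frame(np.zeros(3), np.zeros(3), np.arange(3.0),
                          subpop=["A", "A", "B"])
        with pytest.raises(ValueError):
            stratified_split(df, 0.7)


class TestDetrend:
    def test_planar_values_leave_zero_residuals(self):
        rng = np.random.default_rng(0)
        lons, lats = rng.uniform(-100, -60, 30), rng.uniform(55, 75, 30)
        vals = 3.0 - 0.2 * lons + 0.5 * lats
        resid, beta = detrend(record_frame(lons, lats, vals), "d13C")
        np.testing.assert_allclose(resid["residual"], 0.0, atol=1e-9)
        np.testing.assert_allclose(beta, [3.0, -0.2, 0.5], atol=1e-9)

    def test_trend_free_data_gives_null_coefficients(self):
        rng = np.random.default_rng(1)
        betas = []
        for _ in range(40):
            lons, lats = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50)
            _, beta = detrend(record_frame(lons, lats, rng.normal(0, 1, 50)), "d13C")
            betas.append(beta[1:])
        betas = np.asarray(betas)
        # OLS slope sampling SD ~ sigma / (sd(x) sqrt(n)); bound at 3 SE
        se = 1.0 / (np.std(np.random.default_rng(2).uniform(0, 10, 50)) * np.sqrt(50))
        assert np.all(np.abs(betas.mean(axis=0)) < 3 * se / np.sqrt(40))

    def test_back_adding_trend_recovers_input(self):
        rng = np.random.default_rng(3)
        lons, lats = rng.uniform(0, 10, 25), rng.uniform(0, 10, 25)
        vals = 1.0 + lons - lats + rng.normal(0, 0.5, 25)
        resid, beta = detrend(record_frame(lons, lats, vals), "d13C")
        rebuilt = resid["residual"].to_numpy() + evaluate_trend(beta, lons, lats)
        np.testing.assert_allclose(rebuilt, vals, atol=1e-9)

    def test_coincident_locations_raise(self):
        df = record_frame(np.ones(6), np.ones(6), np.arange(6.0))
        with pytest.raises(ValueError):
            detrend(df, "d13C")


class TestEmpiricalVariogram:
    def test_two_value_gap_hand_computed(self):
        # 12 records, two distinct values 0/2 at two sites -> cross-site
        # bins have gamma = (1/2)*mean((0-2)^2) among cross pairs
        lons = np.r_[np.zeros(6), np.full(6, 1.0)]
        df = record_frame(lons, np.zeros(12), np.r_[np.zeros(6), np.full(6, 2.0)])
        df["residual"] = df["d13C"]
        with pytest.warns(UserWarning):
            tab = empirical_variogram(df, n_lags=2, max_dist=200.0)
        cross = tab[tab["h_km"] > 1.0]
        assert cross["gamma"].iloc[0] == pytest.approx(2.0)

    def test_iid_noise_flat_at_variance(self):
        rng = np.random.default_rng(4)
        df = record_frame(rng.uniform(0, 10, 500), rng.uniform(0, 10, 500),
                          rng.normal(0, 2.0, 500))
        df["residual"] = df["d13C"]
        tab = empirical_variogram(df)
        np.testing.assert_allclose(tab["gamma"], 4.0, rtol=0.25)

    def test_identical_values_zero_everywhere(self):
        rng = np.random.default_rng(5)
        df = record_frame(rng.uniform(0, 5, 30), rng.uniform(0, 5, 30), np.ones(30))
        df["residual"] = df["d13C"]
        tab = empirical_variogram(df)
        np.testing.assert_allclose(tab["gamma"], 0.0, atol=1e-15)


class TestVariogramModels:
    def test_kbessel_half_equals_exponential(self):
        h = np.linspace(0.0, 3000.0, 200)
        kb = VariogramModel("kbessel", 0.3, 2.0, 400.0, shape=0.5)
        ex = VariogramModel("exponential", 0.3, 2.0, 400.0)
        np.testing.assert_allclose(kb(h), ex(h), rtol=1e-9, atol=1e-9)

    def test_fit_recovers_exact_exponential_lag_table(self):
        model = VariogramModel("exponential", 0.5, 3.0, 300.0)
        h = np.linspace(30, 1200, 14)
        tab = pd.DataFrame({"h_km": h, "gamma": model(h), "n_pairs": 100})
        fit = fit_variogram(tab, "exponential")
        assert fit.nugget == pytest.approx(0.5, rel=0.01, abs=0.005)
        assert fit.partial_sill == pytest.approx(3.0, rel=0.01)
        assert fit.range_km == pytest.approx(300.0, rel=0.01)

    def test_pure_nugget_table(self):
        rng = np.random.default_rng(6)
        h = np.linspace(40, 900, 12)
        tab = pd.DataFrame({"h_km": h, "gamma": 2.0 + rng.normal(0, 0.02, 12),
                            "n_pairs": 200})
        fit = fit_variogram(tab, "exponential")
        assert fit.nugget + fit.partial_sill * (1 - np.exp(-h[0] / fit.range_km)) == \
            pytest.approx(2.0, abs=0.15)
        assert fit.sill == pytest.approx(2.0, abs=0.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VariogramModel("exponential", -0.1, 1.0, 100.0)
        with pytest.raises(ValueError):
            VariogramModel("kbessel", 0.0, 1.0, 100.0, shape=0.0)
        with pytest.raises(ValueError):
            VariogramModel("gaussian", 0.0, 1.0, 100.0)


class TestKriging:
    vg = VariogramModel("exponential", 0.0, 2.0, 200.0)

    def test_exact_interpolation_with_zero_nugget(self):
        rng = np.random.default_rng(7)
        coords = np.column_stack([rng.uniform(0, 5, 12), rng.uniform(0, 5, 12)])
        z = rng.normal(0, 1, 12)
        ok = OrdinaryKriging(self.vg).fit(coords, z)
        pred, se = ok.predict(coords, return_std=True)
        np.testing.assert_allclose(pred, z, atol=1e-6)
        np.testing.assert_allclose(se, 0.0, atol=1e-4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(8)
        coords = np.column_stack([rng.uniform(0, 8, 15), rng.uniform(0, 8, 15)])
        ok = OrdinaryKriging(self.vg).fit(coords, rng.normal(size=15))
        for lon, lat in [(1.0, 1.0), (4.0, 7.0), (7.9, 0.1)]:
            w, _ = ok.weights(lon, lat)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_pair_averages(self):
        coords = np.array([[0.0, 1.0], [0.0, -1.0]])
        ok = OrdinaryKriging(self.vg).fit(coords, np.array([3.0, 7.0]))
        pred = ok.predict([[0.0, 0.0]])
        assert pred[0] == pytest.approx(5.0, abs=1e-9)

    def test_three_point_weights_match_direct_solve(self):
        """Independent oracle: assemble and solve the 4x4 system by hand."""
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        z = np.array([1.0, 2.0, 0.5])
        vg = VariogramModel("exponential", 0.1, 1.5, 150.0)
        ok = OrdinaryKriging(vg).fit(coords, z)
        target = (1.7, 0.0)
        w, m = ok.weights(*target)
        # direct solve
        d = pairwise_haversine_km(coords[:, 0], coords[:, 1])
        a = np.ones((4, 4))
        a[:3, :3] = vg(d)
        np.fill_diagonal(a[:3, :3], -1e-10 * vg.sill)
        a[3, 3] = 0.0
        g0 = vg(haversine_km(coords[:, 0], coords[:, 1], target[0], target[1]))
        sol = np.linalg.solve(a, np.append(g0, 1.0))
        np.testing.assert_allclose(w, sol[:3], atol=1e-10)
        assert ok.predict([list(target)])[0] == pytest.approx(sol[:3] @ z)

    def test_neighbor_capped_path_matches_full_solve(self):
        rng = np.random.default_rng(9)
        coords = np.column_stack([rng.uniform(0, 6, 30), rng.uniform(0, 6, 30)])
        z = rng.normal(size=30)
        full = OrdinaryKriging(self.vg, max_neighbors=100).fit(coords, z)
        capped = OrdinaryKriging(self.vg, max_neighbors=30).fit(coords, z)
        capped._factor = None  # force the per-point neighbour path
        pts = np.column_stack([rng.uniform(0, 6, 5), rng.uniform(0, 6, 5)])
        np.testing.assert_allclose(full.predict(pts), capped.predict(pts), atol=1e-8)

    def test_duplicate_locations_jittered_or_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        z = np.array([1.0, 2.0, 3.0])
        OrdinaryKriging(self.vg).fit(coords, z)  # jitters silently
        with pytest.raises(ValueError):
            OrdinaryKriging(self.vg, jitter_deg=0.0).fit(coords, z)


class TestEbkSurface:
    @staticmethod
    def _planar_records(n=60, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lons, lats = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
        vals = 5.0 + 0.8 * lons - 0.3 * lats + rng.normal(0, noise, n)
        return record_frame(lons, lats, vals)

    def test_single_sim_full_subset_equals_one_pass(self):
        df = self._planar_records(noise=0.5)
        grid = Grid.from_bbox((0, 0, 10, 10), 1.0)
        surf = ebk_surface(df, "d13C", grid, n_sims=1, subset_size=len(df), seed=1,
                           model="exponential")
        resid, beta = detrend(df, "d13C")
        vg = fit_variogram(empirical_variogram(resid), "exponential")
        pred, _ = krige_predict(resid, vg, grid)
        lon, lat = grid.meshgrid()
        expected = pred.values + evaluate_trend(beta, lon, lat).reshape(grid.nrows,
                                                                        grid.ncols)
        np.testing.assert_allclose(surf.prediction.values, expected, atol=1e-9)

    def test_noiseless_plane_recovered_everywhere(self):
        df = self._planar_records(noise=0.0)
        grid = Grid.from_bbox((0, 0, 10, 10), 1.0)
        surf = ebk_surface(df, "d13C", grid, n_sims=5, subset_size=40, seed=2,
                           model="exponential")
        lon, lat = grid.meshgrid()
        truth = 5.0 + 0.8 * lon - 0.3 * lat
        np.testing.assert_allclose(surf.prediction.values, truth, atol=1e-5)
        assert np.nanmax(surf.prediction_se.values) < 1e-3

    def test_seed_determinism(self):
        df = self._planar_records(noise=1.0)
        grid = Grid.from_bbox((0, 0, 10, 10), 2.0)
        a = ebk_surface(df, "d13C", grid, n_sims=4, subset_size=40, seed=3)
        b = ebk_surface(df, "d13C", grid, n_sims=4, subset_size=40, seed=3)
        np.testing.assert_array_equal(a.prediction.values, b.prediction.values)
        np.testing.assert_array_equal(a.prediction_se.values, b.prediction_se.values)

    def test_se_positive_away_from_data(self, plateau_run):
        surf = plateau_run["surfaces"][0]
        se = surf.prediction_se.values
        assert np.all(se[np.isfinite(se)] >= 0)
        assert np.nanmean(se) > 0  # strictly positive off-data


class TestAlignRasters:
    @staticmethod
    def _iso(isotope, grid, values, se=None):
        return Isoscape(isotope, grid, Raster(grid, values),
                        Raster(grid, se if se is not None else np.zeros_like(values)),
                        np.zeros(3), VariogramModel("exponential", 0.0, 1.0, 100.0))

    def test_already_aligned_unchanged(self):
        grid = Grid.from_bbox((0, 0, 4, 4), 1.0)
        vals = np.arange(16.0).reshape(4, 4)
        stack = align_rasters([self._iso("d13C", grid, vals)])
        np.testing.assert_allclose(stack.predictions["d13C"].values, vals)
        assert stack.grid == grid

    def test_constant_survives_resampling_to_coarser_grid(self):
        fine = Grid.from_bbox((0, 0, 4, 4), 0.5)
        coarse = Grid.from_bbox((0, 0, 4, 4), 1.0)
        stack = align_rasters([
            self._iso("d13C", fine, np.full((8, 8), 7.0)),
            self._iso("d15N", coarse, np.ones((4, 4))),
        ])
        assert stack.grid.cell == 1.0
        np.testing.assert_allclose(stack.predictions["d13C"].values, 7.0)

    def test_hole_masked_in_all_layers(self):
        grid = Grid.from_bbox((0, 0, 4, 4), 1.0)
        a = np.ones((4, 4))
        a[2, 2] = np.nan
        stack = align_rasters([self._iso("d13C", grid, a),
                               self._iso("d15N", grid, np.ones((4, 4)))])
        assert np.isnan(stack.predictions["d15N"].values[2, 2])
        assert stack.mask[2, 2]

    def test_disjoint_extents_raise(self):
        g1 = Grid.from_bbox((0, 0, 2, 2), 1.0)
        g2 = Grid.from_bbox((10, 10, 12, 12), 1.0)
        with pytest.raises(ValueError):
            align_rasters([self._iso("d13C", g1, np.ones((2, 2))),
                           self._iso("d15N", g2, np.ones((2, 2)))])
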
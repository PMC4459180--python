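"""Geographically weighted regression: kernel, local fits, bandwidth, TGV, ANOVA."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from sklearn.metrics.pairwise import haversine_distances

from ballastgwr.ballast_gwr import (
    DegenerateBandwidthError,
    KernelSpec,
    adaptive_gaussian_weights,
    anova_gwr_vs_mlra,
    distance_matrix,
    fit_gwr,
    fit_local,
    great_circle_distance,
    select_bandwidth,
    test_geographical_variability,
)
from ballastgwr.ballast_mlra import fit_mlra
from ballastgwr.data_io import StationTable
from ballastgwr.synthetic import generate_table
from conftest import calibration_config, make_random_table
from test_mlra import normal_equations_oracle


class TestGreatCircle:
    def test_identical_points_have_zero_distance(self):
        assert great_circle_distance(12.0, 34.0, 12.0, 34.0) == 0.0

    def test_one_degree_on_the_equator(self):
        assert great_circle_distance(0, 0, 0, 1) == pytest.approx(
            2 * math.pi * 6371.0 / 360.0, rel=1e-6
        )

    def test_pole_to_pole(self):
        assert great_circle_distance(90, 0, -90, 0) == pytest.approx(math.pi * 6371.0, rel=1e-6)

    def test_matches_sklearn_haversine_on_random_points(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-89, 89, 25)
        lon = rng.uniform(-180, 180, 25)
        ours = great_circle_distance(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        theirs = haversine_distances(np.radians(np.column_stack([lat, lon]))) * 6371.0
        assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-6)

    def test_symmetry(self):
        assert great_circle_distance(10, 20, -30, 40) == pytest.approx(
            great_circle_distance(-30, 40, 10, 20)
        )

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            great_circle_distance(95, 0, 0, 0)


class TestAdaptiveWeights:
    def test_target_weight_is_one_and_kernel_closed_form(self, small_table):
        kernel = KernelSpec(n_neighbors=6)
        i = 2
        w = adaptive_gaussian_weights(i, small_table, kernel)
        assert w[i] == pytest.approx(1.0)
        d = distance_matrix(small_table)[i]
        h = np.sort(d)[5]
        j = int(np.argmin(np.abs(d - h)))
        assert w[j] == pytest.approx(math.exp(-0.5 * (d[j] / h) ** 2))
        # at exactly d = h the weight is exp(-1/2)
        assert math.exp(-0.5) == pytest.approx(0.6065, abs=1e-4)

    def test_weights_decrease_with_distance_brute_force_sort(self):
        table = make_random_table(30, seed=9)
        kernel = KernelSpec(n_neighbors=10)
        d = distance_matrix(table)[4]
        w = adaptive_gaussian_weights(4, table, kernel)
        order = np.argsort(d)
        assert all(np.diff(w[order]) <= 1e-15)

    def test_station_relabeling_permutes_weights_identically(self):
        table = make_random_table(15, seed=2)
        perm = np.random.default_rng(1).permutation(15)
        permuted = StationTable([table.records[i] for i in perm])
        kernel = KernelSpec(n_neighbors=7)
        w = adaptive_gaussian_weights(3, table, kernel)
        # station 3 of the original sits at position perm^-1(3) in the permuted table
        pos = int(np.argwhere(perm == 3)[0, 0])
        w_p = adaptive_gaussian_weights(pos, permuted, kernel)
        assert w_p == pytest.approx(w[perm], rel=1e-12)

    def test_colocated_neighbor_set_raises_degenerate_bandwidth(self):
        table = make_random_table(10, seed=0)
        recs = [dataclasses.replace(r, lat=10.0, lon=20.0, station_id=f"C{i}")
                for i, r in enumerate(table.records)]
        with pytest.raises(DegenerateBandwidthError, match="jitter|raise"):
            adaptive_gaussian_weights(0, StationTable(recs), KernelSpec(n_neighbors=6))

    def test_neighbor_count_cannot_exceed_table(self, small_table):
        with pytest.raises(ValueError):
            adaptive_gaussian_weights(0, small_table, KernelSpec(n_neighbors=9))


class TestFitLocal:
    def test_uniform_weights_reproduce_global_ols(self):
        table = make_random_table(20, seed=5)
        beta, _ = fit_local(0, table, np.ones(20))
        assert beta == pytest.approx(fit_mlra(table).coefficients, rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 3, 12])
    def test_matches_brute_force_weighted_normal_equations(self, seed):
        table = make_random_table(8, seed=seed)
        rng = np.random.default_rng(seed + 100)
        w = rng.uniform(0.05, 1.0, 8)
        beta, _ = fit_local(2, table, w)
        oracle = normal_equations_oracle(table.design_matrix(), table.column("f_poc"), w)
        assert beta == pytest.approx(oracle, rel=1e-8)

    def test_hat_row_sums_to_one_with_intercept_and_uniform_weights(self):
        table = make_random_table(12, seed=7)
        _, hat_row = fit_local(4, table, np.ones(12))
        assert hat_row.sum() == pytest.approx(1.0, rel=1e-9)

    def test_hat_row_dot_y_is_the_fitted_value(self):
        table = make_random_table(15, seed=8)
        w = adaptive_gaussian_weights(6, table, KernelSpec(n_neighbors=8))
        beta, hat_row = fit_local(6, table, w)
        y = table.column("f_poc")
        assert hat_row @ y == pytest.approx(table.design_matrix()[6] @ beta, rel=1e-10)


class TestFitGwr:
    def test_uniform_weight_gwr_collapses_to_global_fit(self):
        table = make_random_table(25, seed=3)
        glob = fit_mlra(table)
        gwr = fit_gwr(table, KernelSpec(n_neighbors=25), uniform_weights=True)
        for i in range(25):
            assert gwr.local_coefficients[i] == pytest.approx(glob.coefficients, abs=1e-8)
        assert gwr.r2 == pytest.approx(glob.r2, abs=1e-10)
        assert gwr.trace_s == pytest.approx(4.0, abs=1e-8)

    def test_trace_decreases_as_bandwidth_grows(self, studylike):
        table, _ = studylike
        traces = [fit_gwr(table, KernelSpec(nn)).trace_s for nn in (8, 15, 25, 40, 60, 95)]
        assert all(np.diff(traces) < 1e-9)

    def test_constant_coefficient_truth_recovered_within_three_sigma(self):
        table, _ = generate_table(calibration_config(varying=False, seed=5, n_stations=80))
        kernel = KernelSpec(n_neighbors=30)
        gwr = fit_gwr(table, kernel)
        X = table.design_matrix()
        y = table.column("f_poc")
        dist = distance_matrix(table)
        truth = np.array([0.35, 0.2, 0.1, 50.0])
        for i in range(len(table)):
            w = adaptive_gaussian_weights(i, table, kernel, dist=dist)
            A = np.linalg.inv(X.T @ (X * w[:, None]))
            resid = y - X @ gwr.local_coefficients[i]
            sigma2 = float(w @ resid**2) / (w.sum() - 4)
            cov = sigma2 * A @ (X.T @ (X * (w**2)[:, None])) @ A
            se = np.sqrt(np.diag(cov))
            assert np.all(np.abs(gwr.local_coefficients[i] - truth) < 3.0 * se)

    def test_station_relabeling_equivariance(self):
        table = make_random_table(20, seed=13)
        perm = np.random.default_rng(2).permutation(20)
        permuted = StationTable([table.records[i] for i in perm])
        kernel = KernelSpec(n_neighbors=10)
        f1 = fit_gwr(table, kernel)
        f2 = fit_gwr(permuted, kernel)
        assert f2.local_coefficients == pytest.approx(f1.local_coefficients[perm], rel=1e-9)
        assert f2.trace_s == pytest.approx(f1.trace_s, rel=1e-9)

    def test_residuals_and_fitted_recompose_observations(self, studylike):
        table, _ = studylike
        gwr = fit_gwr(table, KernelSpec(n_neighbors=30))
        assert gwr.fitted + gwr.residuals == pytest.approx(table.column("f_poc"), rel=1e-12)
        assert gwr.rss == pytest.approx(float(gwr.residuals @ gwr.residuals))


class TestBandwidthSelection:
    def test_golden_section_matches_exhaustive_oracle(self):
        table, _ = generate_table(calibration_config(varying=True, seed=7, n_stations=40))
        kernel, _ = select_bandwidth(table)
        exhaustive = {nn: fit_gwr(table, KernelSpec(nn)).aicc for nn in range(6, 41)}
        best_val = min(exhaustive.values())
        best_nn = max(nn for nn, v in exhaustive.items() if v <= best_val + 1e-9)
        assert kernel.n_neighbors == best_nn

    def test_constant_truth_prefers_large_bandwidths(self):
        # no spatial structure: the smoothest models win the AICc race
        table, _ = generate_table(calibration_config(varying=False, seed=100, n_stations=80))
        kernel, _ = select_bandwidth(table)
        assert kernel.n_neighbors > 40

    def test_empty_search_range_rejected(self, studylike):
        table, _ = studylike
        with pytest.raises(ValueError):
            select_bandwidth(table, n_min=50, n_max=50)

    def test_profile_contains_selected_bandwidth(self, studylike):
        table, _ = studylike
        kernel, profile = select_bandwidth(table)
        assert kernel.n_neighbors in [nn for nn, _ in profile]


class TestGeographicalVariability:
    def test_varying_term_flagged_and_constant_terms_not(self):
        # light version of the calibration study (deep version in acceptance)
        hits = 0
        for seed in range(10):
            table, _ = generate_table(calibration_config(varying=True, seed=seed))
            kernel, _ = select_bandwidth(table)
            tgv = {r.term: r.diff_of_criterion for r in test_geographical_variability(table, kernel)}
            if tgv["pic"] < -2 and tgv["bsi"] > -2 and tgv["lith"] > -2:
                hits += 1
        assert hits >= 8

    def test_all_constant_truth_rarely_flagged(self):
        hits = 0
        for seed in range(10):
            table, _ = generate_table(calibration_config(varying=False, seed=500 + seed))
            kernel, _ = select_bandwidth(table)
            tgv = test_geographical_variability(table, kernel)
            if all(r.diff_of_criterion >= -2 for r in tgv):
                hits += 1
        assert hits >= 7

    def test_backfitting_converges_and_reports_iterations(self, studylike):
        table, _ = studylike
        results = test_geographical_variability(table, KernelSpec(n_neighbors=30))
        assert [r.term for r in results] == ["pic", "bsi", "lith", "intercept"]
        assert all(r.converged for r in results)
        assert all(1 <= r.n_iter <= 100 for r in results)


class TestAnova:
    def test_uniform_weight_gwr_yields_zero_f_and_flag(self):
        table = make_random_table(30, seed=21)
        glob = fit_mlra(table)
        gwr = fit_gwr(table, KernelSpec(n_neighbors=30), uniform_weights=True)
        res = anova_gwr_vs_mlra(glob, gwr)
        assert res.f_stat == 0.0 and not res.improved

    def test_f_exceeds_permutation_null_on_varying_coefficients(self, studylike):
        from ballastgwr.synthetic import default_study_config

        cfg = default_study_config(seed=11)
        cfg.n_stations = 100
        table, _ = generate_table(cfg)
        glob = fit_mlra(table)
        kernel, _ = select_bandwidth(table)
        f_obs = anova_gwr_vs_mlra(glob, fit_gwr(table, kernel)).f_stat
        rng = np.random.default_rng(0)
        null_f = []
        for _ in range(99):
            perm = rng.permutation(len(table))
            recs = [
                dataclasses.replace(table[i], lat=table[int(perm[i])].lat, lon=table[int(perm[i])].lon)
                for i in range(len(table))
            ]
            shuffled = StationTable(recs)
            null_f.append(
                anova_gwr_vs_mlra(fit_mlra(shuffled), fit_gwr(shuffled, kernel)).f_stat
            )
        assert f_obs > np.quantile(null_f, 0.99)

    def test_reported_degrees_of_freedom(self, studylike):
        table, _ = studylike
        glob = fit_mlra(table)
        gwr = fit_gwr(table, KernelSpec(n_neighbors=30))
        res = anova_gwr_vs_mlra(glob, gwr)
        assert res.df1 == len(table) - 4
        assert res.df2 == round(len(table) - gwr.trace_s)
        assert res.nu1 == pytest.approx(gwr.trace_s - 4)
        assert 0 <= res.p_value <= 1
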
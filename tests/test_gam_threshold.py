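"""Spline basis/penalty construction, the penalized partially linear fit,
and the AIC-grid change-point scan."""

import warnings

import numpy as np
import pytest

from vitd_uacr import (GeneratorConfig, build_design, build_spline_basis,
                       fit_pgam, generate_cohort, plot_threshold_gam,
                       threshold_scan)
from vitd_uacr.gam_threshold import _greville, gaussian_aic


def deboor(x, knots, degree, j):
    """Independent Cox-de Boor recursion for B_{j,degree}(x)."""
    if degree == 0:
        return 1.0 if knots[j] <= x < knots[j + 1] else 0.0
    left = 0.0
    if knots[j + degree] > knots[j]:
        left = (x - knots[j]) / (knots[j + degree] - knots[j]) * deboor(x, knots, degree - 1, j)
    right = 0.0
    if knots[j + degree + 1] > knots[j + 1]:
        right = ((knots[j + degree + 1] - x) / (knots[j + degree + 1] - knots[j + 1])
                 * deboor(x, knots, degree - 1, j + 1))
    return left + right


class TestSplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(0, 30, 400)
        B, _, _ = build_spline_basis(x, dimension=12)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_matches_deboor_recursion(self, rng):
        x = rng.uniform(0, 10, 120)
        B, _, knots = build_spline_basis(x, dimension=8, degree=3)
        # interior evaluation points dodge the right-endpoint convention
        probe = np.quantile(x, [0.1, 0.35, 0.6, 0.85])
        Bp, _, _ = build_spline_basis(x, dimension=8, degree=3)
        for xv in probe:
            row = [deboor(xv, knots, 3, j) for j in range(8)]
            from scipy.interpolate import BSpline
            got = BSpline.design_matrix(np.array([xv]), knots, 3).toarray()[0]
            np.testing.assert_allclose(got, row, atol=1e-12)

    def test_penalty_null_space_is_linear_in_x(self, rng):
        x = rng.normal(20, 8, 300)
        B, P, knots = build_spline_basis(x, dimension=10, degree=3)
        xi = _greville(knots, 3)
        gamma_lin = 2.0 + 0.7 * xi       # coefficients linear in the Greville points
        assert gamma_lin @ P @ gamma_lin == pytest.approx(0.0, abs=1e-10)
        # and the resulting spline is exactly linear in x
        np.testing.assert_allclose(B @ gamma_lin, 2.0 + 0.7 * x, atol=1e-9)

    def test_degenerate_inputs(self, rng):
        with pytest.raises(ValueError, match="constant"):
            build_spline_basis(np.ones(50))
        with pytest.raises(ValueError, match="dimension"):
            build_spline_basis(rng.normal(size=50), dimension=3)


class TestFitPgam:
    @staticmethod
    def _data(rng, n=400):
        x = rng.uniform(0, 10, n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 1.0 + 0.5 * X[:, 1] + np.sin(x) + rng.normal(0, 0.3, n)
        return y, X, x

    def test_large_lambda_equals_ols(self, rng):
        y, X, x = self._data(rng)
        fit = fit_pgam(y, X, x, lam=1e12)
        coef, *_ = np.linalg.lstsq(np.column_stack([X, x]), y, rcond=None)
        rss_ols = float(np.sum((y - np.column_stack([X, x]) @ coef) ** 2))
        assert fit.rss == pytest.approx(rss_ols, rel=1e-6)
        assert fit.edf == pytest.approx(3.0, abs=1e-4)

    def test_zero_lambda_equals_unpenalized_ls(self, rng):
        y, X, x = self._data(rng)
        fit = fit_pgam(y, X, x, lam=0.0, basis_dim=8)
        # normal-equations oracle on the same constrained design
        B, _, _ = build_spline_basis(x, dimension=8)
        d = B.shape[1]
        ones = np.ones((d, 1)) / np.sqrt(d)
        Z = np.linalg.qr(np.eye(d) - ones @ ones.T)[0][:, : d - 1]
        M = np.hstack([X, B @ Z])
        coef = np.linalg.solve(M.T @ M, M.T @ y)
        rss = float(np.sum((y - M @ coef) ** 2))
        assert fit.rss == pytest.approx(rss, rel=1e-10)
        np.testing.assert_allclose(fit.coef, coef, atol=1e-8)

    def test_exact_linear_signal_zero_rss(self, rng):
        n = 200
        x = rng.uniform(0, 10, n)
        X = np.ones((n, 1))
        y = 3.0 - 0.4 * x
        for lam in (0.0, 1e2, 1e12):
            fit = fit_pgam(y, X, x, lam=lam, basis_dim=8)
            assert fit.rss == pytest.approx(0.0, abs=1e-6)

    def test_edf_trace_two_ways(self, rng):
        y, X, x = self._data(rng)
        lam = 10.0
        fit = fit_pgam(y, X, x, lam=lam, basis_dim=8)
        B, P, _ = build_spline_basis(x, dimension=8)
        d = B.shape[1]
        ones = np.ones((d, 1)) / np.sqrt(d)
        Z = np.linalg.qr(np.eye(d) - ones @ ones.T)[0][:, : d - 1]
        M = np.hstack([X, B @ Z])
        Pf = np.zeros((M.shape[1], M.shape[1]))
        Pf[X.shape[1]:, X.shape[1]:] = Z.T @ P @ Z
        Ainv = np.linalg.inv(M.T @ M + lam * Pf)
        leverage = np.einsum("ij,jk,ik->i", M, Ainv, M)   # diag of the hat matrix
        trace_direct = float(np.trace(Ainv @ (M.T @ M)))
        assert leverage.sum() == pytest.approx(trace_direct, abs=1e-8)
        assert fit.edf == pytest.approx(trace_direct, abs=1e-8)

    def test_gcv_selects_reasonable_smoothness(self, rng):
        y, X, x = self._data(rng, n=600)
        fit = fit_pgam(y, X, x, lam="auto")
        # sine signal: needs more than the 3-parameter linear limit,
        # less than the saturated basis
        assert 4.0 < fit.edf < 12.0
        assert fit.rss / fit.n < 0.3 ** 2 * 1.5

    def test_smooth_curve_bands_contain_estimate(self, rng):
        y, X, x = self._data(rng)
        fit = fit_pgam(y, X, x, lam="auto")
        curve = fit.smooth_curve(np.linspace(0.5, 9.5, 50))
        assert (curve["lo"] <= curve["fit"]).all()
        assert (curve["fit"] <= curve["hi"]).all()
        # continuity: no jumps on a fine grid
        fine = fit.smooth_curve(np.linspace(0.5, 9.5, 400))
        assert np.max(np.abs(np.diff(fine["fit"]))) < 0.2

    def test_rank_deficient_rejected(self, rng):
        y, X, x = self._data(rng)
        X_bad = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank"):
            fit_pgam(y, X_bad, x)

    def test_aic_tradeoff(self):
        # lower RSS at fixed edf and lower edf at fixed RSS both reduce AIC
        assert gaussian_aic(100, 50.0, 5) < gaussian_aic(100, 60.0, 5)
        assert gaussian_aic(100, 50.0, 5) < gaussian_aic(100, 50.0, 6)


class TestBuildDesign:
    def test_sex_and_season_coding(self, small_cohort):
        X, names = build_design(small_cohort, "demo")
        assert names == ["intercept", "age", "male", "season_summer",
                         "season_autumn", "season_winter"]
        assert set(np.unique(X[:, 2])) <= {0.0, 1.0}

    def test_collinear_columns_named(self, small_cohort):
        with pytest.raises(ValueError, match="bmi"):
            build_design(small_cohort, ["age", "bmi", "bmi"])


class TestThresholdScan:
    def test_grid_arithmetic(self, big_cohort):
        scan = threshold_scan(big_cohort, adjust="none", grid_low=5.0,
                              grid_high=20.0, step=0.2, log_uacr=True)
        assert len(scan.grid) == 76
        np.testing.assert_allclose(np.diff(scan.grid), 0.2, atol=1e-9)

    def test_recovers_true_threshold(self, big_cohort):
        scan = threshold_scan(big_cohort, adjust="full", grid_low=4.0,
                              grid_high=20.0, step=0.2, log_uacr=True)
        assert scan.selected_tau == pytest.approx(8.0, abs=0.2)
        assert scan.has_threshold and scan.aic_margin > 100

    def test_unadjusted_scan_close_to_truth(self, big_cohort):
        scan = threshold_scan(big_cohort, adjust="none", grid_low=4.0,
                              grid_high=20.0, step=0.2, log_uacr=True)
        assert abs(scan.selected_tau - 8.0) <= 0.4

    def test_null_data_reports_no_threshold(self):
        flat, ptps = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)   # boundary picks expected
            for s in range(1, 7):
                c = generate_cohort(GeneratorConfig(
                    n_subjects=6_000, seed=s, below_threshold_slope=0.0))
                scan = threshold_scan(c, adjust="none", grid_low=4.0,
                                      grid_high=20.0, step=0.2, log_uacr=True)
                flat.append(not scan.has_threshold)
                ptps.append(np.ptp(scan.aic))
        assert sum(flat) >= 4          # AIC rarely beats the no-threshold model
        assert max(ptps) < 10.0        # and the profile is flat within noise

    def test_smooth_variant_agrees(self):
        c = generate_cohort(GeneratorConfig(n_subjects=4_000, seed=21))
        lin = threshold_scan(c, adjust="none", grid_low=5.0, grid_high=12.0,
                             step=0.2, log_uacr=True)
        smo = threshold_scan(c, adjust="none", grid_low=5.0, grid_high=12.0,
                             step=0.2, log_uacr=True, smooth=True)
        assert abs(lin.selected_tau - smo.selected_tau) <= 0.6

    def test_boundary_selection_warns(self, big_cohort):
        with pytest.warns(UserWarning, match="boundary"):
            threshold_scan(big_cohort, adjust="none", grid_low=10.0,
                           grid_high=14.0, step=0.2, log_uacr=True)

    def test_grid_outside_support_rejected(self, big_cohort):
        with pytest.raises(ValueError, match="support"):
            threshold_scan(big_cohort, adjust="none", grid_low=200.0, grid_high=300.0)

    def test_plot_artifact(self, big_cohort, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            scans = [threshold_scan(big_cohort, adjust=a, grid_low=4.0,
                                    grid_high=20.0, log_uacr=True)
                     for a in ("none", "full")]
        path = plot_threshold_gam(scans, big_cohort, tmp_path / "thr.png",
                                  log_uacr=True)
        assert path.exists() and path.stat().st_size > 0
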
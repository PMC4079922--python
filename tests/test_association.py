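"""Logistic IRLS, categorical odds ratios, lowess, predicted-probability curve."""

import numpy as np
import pytest
from scipy.special import expit, logit

from vitd_uacr import (GeneratorConfig, SeparationError, apply_exclusions,
                       category_or, fit_logistic, generate_cohort, lowess,
                       predicted_probability_curve)


def retained_cohort(**kwargs):
    """Generate a cohort and restrict it to the normoalbuminuric analysis
    population (UACR < 30 mg/g), as every association model expects."""
    cohort = generate_cohort(GeneratorConfig(**kwargs))
    return apply_exclusions(cohort)[0]


@pytest.fixture(scope="module")
def linked():
    return retained_cohort(n_subjects=20_000, seed=31)


def newton_logistic(y, X, tol=1e-12, max_iter=60):
    """Independent Newton-Raphson oracle on the log-likelihood."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p)
        hess = -(X.T * (p * (1 - p))) @ X
        step = np.linalg.solve(hess, -grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # intercept = logit of the event fraction (2,424 events of 14,594)
        y = np.zeros(14_594)
        y[:2_424] = 1.0
        fit = fit_logistic(y, np.ones((len(y), 1)))
        assert fit.coef[0] == pytest.approx(logit(2_424 / 14_594), abs=1e-10)
        assert fit.coef[0] == pytest.approx(-1.614, abs=5e-4)

    def test_two_by_two_equals_cross_product_ratio(self):
        # published two-group diabetes counts: 1,001/12,170 in normal UAE,
        # 348/2,424 in high-normal UAE
        y = np.concatenate([np.zeros(12_170), np.ones(2_424)])
        x = np.concatenate([np.r_[np.ones(1_001), np.zeros(11_169)],
                            np.r_[np.ones(348), np.zeros(2_076)]])
        fit = fit_logistic(y, np.column_stack([np.ones_like(y), x]))
        or_closed = (348 * 11_169) / (1_001 * 2_076)
        assert np.exp(fit.coef[1]) == pytest.approx(or_closed, rel=1e-9)
        assert or_closed == pytest.approx(1.870, abs=5e-4)

    def test_matches_newton_oracle(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        beta_true = np.array([-0.5, 0.8, -0.3, 0.2])
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)
        fit = fit_logistic(y, X)
        np.testing.assert_allclose(fit.coef, newton_logistic(y, X), atol=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < expit(X @ np.array([0.2, -0.6, 0.4]))).astype(float)
        fit = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.se(), ref.bse, atol=1e-6)

    def test_degenerate_outcome(self):
        with pytest.raises(SeparationError, match="identical"):
            fit_logistic(np.zeros(50), np.ones((50, 1)))

    def test_complete_separation_detected(self):
        x = np.linspace(-2, 2, 80)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError, match="separation"):
            fit_logistic(y, np.column_stack([np.ones(80), x]))

    def test_wald_ci_contains_or(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ np.array([-1.0, 0.5]))).astype(float)
        fit = fit_logistic(y, X)
        b, se = fit.coef[1], fit.se()[1]
        lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
        assert lo < np.exp(b) < hi


class TestCategoryOr:
    def test_reference_row_contract(self, linked):
        for scheme in ("quartile", "percentile", "clinical"):
            rows = category_or(linked, scheme, adjust="none")
            ref = [r for r in rows if r.is_reference]
            assert len(ref) == 1
            assert ref[0].oratio == 1.0 and ref[0].ci_low is None
            assert ref[0].level == rows[-1].level

    def test_lowest_category_elevated_and_gradient(self, linked):
        rows = category_or(linked, "quartile", adjust="none")
        ors = [r.oratio for r in rows]
        assert ors[0] > 1.1                      # lowest quartile carries the risk
        assert ors[0] >= max(ors[1:]) - 0.1      # non-increasing toward reference
        for r in rows[:-1]:
            assert r.ci_low < r.oratio < r.ci_high

    def test_null_generator_cis_cover_unity(self):
        covered = total = 0
        for s in range(1, 21):
            c = retained_cohort(n_subjects=3_000, seed=s, below_threshold_slope=0.0)
            for r in category_or(c, "quartile", adjust="none"):
                if r.is_reference or r.omitted:
                    continue
                total += 1
                covered += int(r.ci_low <= 1.0 <= r.ci_high)
        assert covered / total >= 0.9

    def test_diabetes_stratification(self, linked):
        rows = category_or(linked, "clinical", adjust="full",
                           stratify_by_diabetes=True)
        strata = {r.stratum for r in rows}
        assert strata == {"diabetes", "no-diabetes"}
        # per-cell ns add up to the full cohort within each level
        pooled = category_or(linked, "clinical", adjust="full")
        for level in {r.level for r in pooled}:
            n_split = sum(r.n for r in rows if r.level == level)
            n_all = sum(r.n for r in pooled if r.level == level)
            assert n_split == n_all

    def test_zero_event_category_omitted(self):
        c = retained_cohort(n_subjects=400, seed=5, below_threshold_slope=0.0)
        # force zero events in the lowest quartile
        q1 = np.quantile(c["serum_25ohd"], 0.25)
        c = c.copy()
        c.loc[c["serum_25ohd"] <= q1, "uacr"] = 5.0
        rows = category_or(c, "quartile", adjust="none")
        assert rows[0].omitted and rows[0].oratio is None


class TestLowess:
    def test_reproduces_linear_exactly(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2.0 * x + 1.0
        for frac in (0.2, 0.5, 1.0):
            np.testing.assert_allclose(lowess(x, y, frac=frac), y, atol=1e-8)

    def test_constant_reproduced(self, rng):
        x = rng.uniform(0, 10, 25)
        np.testing.assert_allclose(lowess(x, np.full(25, 3.7)), 3.7, atol=1e-12)

    def test_matches_per_point_wls_oracle(self, rng):
        x = np.sort(rng.uniform(0, 10, 30))
        y = np.sin(x) + rng.normal(0, 0.1, 30)
        frac = 0.5
        got = lowess(x, y, frac=frac, it=0)
        k = int(np.ceil(frac * len(x)))
        for i in range(len(x)):
            dist = np.abs(x - x[i])
            dk = np.sort(dist)[k - 1]
            w = np.clip(1 - (dist / dk) ** 3, 0, None) ** 3
            # weighted straight-line fit via the normal equations
            W = np.diag(w)
            A = np.column_stack([np.ones_like(x), x - x[i]])
            coef = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
            assert got[i] == pytest.approx(coef[0], abs=1e-8)

    def test_robustness_downweights_outlier(self, rng):
        x = np.linspace(0, 10, 60)
        y = x + rng.normal(0, 0.2, 60)
        y[30] += 50.0
        smooth_rob = lowess(x, y, frac=0.4, it=3)
        smooth_raw = lowess(x, y, frac=0.4, it=0)
        i_near = 29
        assert abs(smooth_rob[i_near] - x[i_near]) < abs(smooth_raw[i_near] - x[i_near])

    def test_statsmodels_cross_check(self, rng):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
        x = np.sort(rng.uniform(0, 10, 150))
        y = np.sin(x) + rng.normal(0, 0.05, 150)
        ours = lowess(x, y, frac=0.4, it=0)
        ref = sm_lowess(y, x, frac=0.4, it=0, return_sorted=False)
        assert np.mean(np.abs(ours - ref)) < 0.02

    def test_input_validation(self, rng):
        x = rng.uniform(0, 1, 20)
        with pytest.raises(ValueError, match="span"):
            lowess(x, x, frac=0.05)
        with pytest.raises(ValueError, match="at least 10"):
            lowess(x[:5], x[:5])
        with pytest.raises(ValueError, match="span fraction"):
            lowess(x, x, frac=1.5)


class TestPredictedProbabilityCurve:
    def test_covariate_free_curve_is_constant_prevalence(self):
        c = retained_cohort(n_subjects=3_000, seed=41)
        curve = predicted_probability_curve(c, adjust="none", n_boot=5, seed=0,
                                            include_vitd_spline=False)
        from vitd_uacr import classify_uae
        prev = np.mean(np.asarray(classify_uae(c["uacr"].to_numpy())) == "high_normal")
        np.testing.assert_allclose(curve.prob, prev, atol=1e-10)

    def test_decreasing_then_flat_around_threshold(self):
        c = retained_cohort(n_subjects=12_000, seed=43)
        curve = predicted_probability_curve(c, adjust="none", n_boot=5, seed=0,
                                            frac=0.3)
        g, p = curve.grid, curve.prob
        slopes = np.diff(p) / np.diff(g)
        below = g[:-1] < 6.0
        above = g[:-1] > 10.0
        assert slopes[below].mean() < -0.005          # risk falls as D rises below tau*
        assert abs(slopes[above].mean()) < 0.005      # flat above tau*
        assert ((curve.lo <= curve.prob) & (curve.prob <= curve.hi)).all()
        assert ((curve.prob > 0) & (curve.prob < 1)).all()

    def test_band_shrinks_with_n(self):
        widths = []
        for n in (2_000, 8_000):
            c = retained_cohort(n_subjects=n, seed=47)
            curve = predicted_probability_curve(c, adjust="none", n_boot=30,
                                                seed=1, grid_size=40)
            widths.append(np.mean(curve.hi - curve.lo))
        assert widths[1] < widths[0]

    def test_seeded_bootstrap_reproducible(self):
        c = retained_cohort(n_subjects=2_000, seed=53)
        a = predicted_probability_curve(c, adjust="none", n_boot=10, seed=7)
        b = predicted_probability_curve(c, adjust="none", n_boot=10, seed=7)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)
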
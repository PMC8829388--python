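import numpy as np
import pytest

from befgrass.stats_models import (
    ModelFitResult,
    PiecewiseFit,
    PiecewiseRegressor,
    classify_shape,
    compare_models,
    davies_test,
    fit_linear,
    fit_piecewise,
    fit_quadratic,
    select_best,
)


def _broken_line(x, a, b1, b2, psi):
    return a + b1 * x + (b2 - b1) * np.clip(x - psi, 0, None)


class TestOlsFits:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 5, 30)
        f = fit_linear(x, 2 * x + 1)
        assert f.coef["slope"] == pytest.approx(2.0)
        assert f.coef["intercept"] == pytest.approx(1.0)
        assert f.r2 == pytest.approx(1.0)

    def test_pure_parabola_on_symmetric_x(self):
        x = np.linspace(-2, 2, 41)
        q = fit_quadratic(x, x**2)
        assert q.coef["curvature"] == pytest.approx(1.0)
        lin = fit_linear(x, x**2)
        assert lin.coef["slope"] == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        y = 1.5 - 0.7 * x + rng.normal(size=50)
        f = fit_linear(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.coef["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert f.coef["slope"] == pytest.approx(beta[1], abs=1e-10)
        q = fit_quadratic(x, y)
        Xq = np.column_stack([np.ones_like(x), x, x**2])
        bq = np.linalg.solve(Xq.T @ Xq, Xq.T @ y)
        assert q.coef["curvature"] == pytest.approx(bq[2], abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(np.ones(10), np.arange(10.0))

    def test_nesting_rss_inequalities(self):
        rng = np.random.default_rng(5)
        for s in range(5):
            x = rng.uniform(0, 2, 80)
            y = rng.normal(size=80) + 0.3 * x
            rl = fit_linear(x, y).rss
            assert fit_quadratic(x, y).rss <= rl + 1e-9
            assert fit_piecewise(x, y, with_davies=False).rss <= rl + 1e-9


class TestPiecewise:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, 120)
        y = _broken_line(x, 2.0, 0.0, 1.2, 1.0)
        f = fit_piecewise(x, y, with_davies=False)
        assert f.breakpoint == pytest.approx(1.0, abs=1e-6)
        assert f.left_slope == pytest.approx(0.0, abs=1e-8)
        assert f.right_slope == pytest.approx(1.2, abs=1e-8)

    def test_sklearn_contract(self):
        reg = PiecewiseRegressor(min_segment=3)
        params = reg.get_params()
        assert params["min_segment"] == 3
        reg.set_params(min_segment=5)
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 2, 100)
        y = _broken_line(x, 1, 0.2, 1.5, 0.9) + rng.normal(0, 0.05, 100)
        reg.fit(x.reshape(-1, 1), y)
        pred = reg.predict(np.array([[0.5], [1.5]]))
        assert pred.shape == (2,)
        assert reg.breakpoint_ == pytest.approx(0.9, abs=0.1)

    def test_ci_coverage_at_moderate_noise(self):
        # noise sd 0.1, n = 300: the delta-method CI must cover the true
        # breakpoint in at least 90% of replicates
        cover = 0
        inside_own = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            x = rng.uniform(0, 2, 300)
            y = _broken_line(x, 2, 0.0, 1.2, 1.0) + rng.normal(0, 0.1, 300)
            reg = PiecewiseRegressor().fit(x, y)
            lo, hi = reg.breakpoint_ci_
            cover += lo <= 1.0 <= hi
            inside_own += lo <= reg.breakpoint_ <= hi
        assert inside_own == 100  # CI always contains its point estimate
        assert cover >= 90

    def test_linear_data_selects_linear_despite_nesting(self):
        rng = np.random.default_rng(3)
        picked = []
        for s in range(20):
            r = np.random.default_rng(s)
            x = r.uniform(0, 2, 200)
            y = 1 + 0.5 * x + r.normal(0, 0.3, 200)
            comp = compare_models(x, y)
            assert comp.fits["piecewise"].r2 >= comp.fits["linear"].r2 - 1e-9
            picked.append(comp.best)
        assert picked.count("linear") >= 18

    def test_too_few_interior_points_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError):
            PiecewiseRegressor(min_segment=5).fit(x, x * 2)

    def test_breakpoint_estimator_consistency(self):
        # median absolute error shrinks from n=100 to n=1000
        errs = {100: [], 1000: []}
        for n in errs:
            for s in range(20):
                rng = np.random.default_rng(1000 * n + s)
                x = rng.uniform(0, 2, n)
                y = _broken_line(x, 2, 0.1, 1.0, 1.0) + rng.normal(0, 0.3, n)
                f = PiecewiseRegressor().fit(x, y)
                errs[n].append(abs(f.breakpoint_ - 1.0))
        assert np.median(errs[1000]) < np.median(errs[100])


class TestDavies:
    def test_high_power_on_strong_break(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 2, 300)
        y = _broken_line(x, 2, 0.0, 1.2, 1.0) + rng.normal(0, 0.05, 300)
        assert davies_test(x, y) < 0.001

    def test_type_one_error_controlled(self):
        # simulated at the survey's regression sample size (581 quadrats),
        # where the Gaussian-process approximation behind the bound holds
        rejections = 0
        n_sim = 500
        for s in range(n_sim):
            rng = np.random.default_rng(s)
            x = rng.uniform(0, 2, 581)
            y = 1 + 0.5 * x + rng.normal(0, 0.3, 581)
            rejections += davies_test(x, y) <= 0.05
        rate = rejections / n_sim
        assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            davies_test(np.arange(5.0), np.arange(5.0))

    def test_agrees_with_aic_rule_on_strong_breaks(self):
        agree = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            x = rng.uniform(0, 2, 300)
            y = _broken_line(x, 2, 0.0, 1.2, 1.0) + rng.normal(0, 0.1, 300)
            comp = compare_models(x, y)
            agree += (comp.best == "piecewise") and (
                comp.fits["piecewise"].davies_p < 0.05
            )
        assert agree >= 48  # >= 95% qualitative agreement


class TestSelection:
    def _fake_fit(self, model, aic, r2=0.5, n=100):
        common = dict(coef={}, se={}, r2=r2, p_overall=0.01, p_sig=0.01,
                      aic=aic, rss=1.0, n=n, x_range=(0.0, 1.0))
        if model == "piecewise":
            return PiecewiseFit(model=model, breakpoint=0.5,
                                breakpoint_ci=(0.4, 0.6), left_slope=0.0,
                                left_slope_ci=(-0.1, 0.1), right_slope=1.0,
                                right_slope_ci=(0.8, 1.2), **common)
        if model == "quadratic":
            return ModelFitResult(
                model=model, **{**common, "coef": {"slope": 0.1, "curvature": 1.0}})
        return ModelFitResult(model=model, slope_ci=(0.1, 0.2), **common)

    def test_identical_aic_ties_break_to_linear(self):
        fits = {m: self._fake_fit(m, 100.0) for m in ("linear", "quadratic", "piecewise")}
        assert select_best(fits).best == "linear"

    def test_marginally_better_nonlinear_still_loses(self):
        fits = {
            "linear": self._fake_fit("linear", 100.0),
            "quadratic": self._fake_fit("quadratic", 96.0, r2=0.6),
            "piecewise": self._fake_fit("piecewise", 95.5, r2=0.62),
        }
        assert select_best(fits).best == "linear"

    def test_decisive_nonlinear_wins_with_r2_tiebreak(self):
        fits = {
            "linear": self._fake_fit("linear", 100.0),
            "quadratic": self._fake_fit("quadratic", 93.0, r2=0.60),
            "piecewise": self._fake_fit("piecewise", 91.0, r2=0.63),
        }
        comp = select_best(fits)
        assert comp.best == "piecewise"

    def test_mismatched_n_rejected(self):
        fits = {
            "linear": self._fake_fit("linear", 100.0, n=100),
            "quadratic": self._fake_fit("quadratic", 90.0, n=99),
            "piecewise": self._fake_fit("piecewise", 95.0, n=100),
        }
        with pytest.raises(ValueError, match="sample sizes"):
            select_best(fits)


class TestShapeLabels:
    def _pw(self, left_ci, right_ci, psi):
        return PiecewiseFit(
            model="piecewise", coef={}, se={}, r2=0.3, p_overall=0.001, p_sig=0.001,
            aic=0.0, rss=1.0, n=581, x_range=(0.4, 1.6),
            breakpoint=psi, breakpoint_ci=(psi - 0.1, psi + 0.1),
            left_slope=np.mean(left_ci), left_slope_ci=left_ci,
            right_slope=np.mean(right_ci), right_slope_ci=right_ci,
        )

    def test_flat_then_rising_segments(self):
        # slope CIs straddling zero then clearly positive
        fit = self._pw((-0.17, 0.25), (0.94, 1.38), 1.05)
        assert classify_shape(fit) == "Unchange + Increase (1.05)"

    def test_rising_then_flat_segments(self):
        fit = self._pw((0.09, 0.15), (-0.14, 0.01), 1.11)
        assert classify_shape(fit) == "Increase + Unchange (1.11)"

    def test_symmetric_ci_is_unchange(self):
        lin = ModelFitResult(
            model="linear", coef={"slope": 0.0, "intercept": 0.0},
            se={}, r2=0.0, p_overall=0.9, p_sig=0.9, aic=0.0, rss=1.0, n=50,
            x_range=(0.0, 1.0), slope_ci=(-0.2, 0.2),
        )
        assert classify_shape(lin) == "Unchange"

    def test_quadratic_vertex_inside_range_is_u_type(self):
        x = np.linspace(-2, 2, 50)
        q = fit_quadratic(x, (x - 0.2) ** 2)
        assert classify_shape(q) == "U-type"
        q2 = fit_quadratic(x, -((x + 0.3) ** 2))
        assert classify_shape(q2) == "Unimodal"

    def test_quadratic_vertex_outside_range_is_monotone(self):
        x = np.linspace(0, 1, 50)
        q = fit_quadratic(x, (x + 5) ** 2)
        assert classify_shape(q) == "Increase"
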
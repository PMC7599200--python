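"""Predictive metrics, LOOCV, jackknifed AUC and behavioral diagnostics."""

import math

import numpy as np
import pytest

from cbschoice.bezier import BezierPiece, CBSCurve, eval_curve
from cbschoice.fitting import ChoiceDataset, FitConfig, fit_model
from cbschoice.metrics import (
    IneligibleSessionError,
    UndefinedMetricError,
    accuracy,
    auc_with_jackknife,
    avg_discount_rate_change,
    count_risk_switches,
    discount_rate_at,
    in_sample_metrics,
    jackknife_se,
    loocv_evaluate,
    risk_aversion_at,
    tjurs_d,
)
from cbschoice.models import (
    CBSSpec,
    ParametricSpec,
    build_cbs_curve,
    recovery_parameter_sets,
)
from cbschoice.simulate import generate_design, simulate_choices

QUICK = FitConfig(n_starts=2, seed=3, maxiter=80, ftol=1e-7)


class TestTjursD:
    def test_derived_mean_difference(self):
        p = np.array([0.9, 0.8, 0.2, 0.3])
        c = np.array([1, 1, 2, 2])
        assert tjurs_d(p, c) == pytest.approx(0.6, abs=1e-12)

    def test_perfect_and_random_models(self):
        c = np.array([1, 2, 1, 2])
        assert tjurs_d(np.where(c == 1, 1.0, 0.0), c) == 1.0
        assert tjurs_d(np.full(4, 0.5), c) == 0.0

    def test_missing_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            tjurs_d(np.array([0.6, 0.7]), np.array([1, 1]))

    def test_class_label_invariance(self):
        p = np.array([0.9, 0.4, 0.2, 0.7])
        c = np.array([1, 2, 2, 1])
        assert tjurs_d(1 - p, 3 - c) == pytest.approx(tjurs_d(p, c), abs=1e-12)


class TestAccuracy:
    def test_tie_rule(self):
        assert accuracy(np.full(6, 0.5), np.array([1, 2] * 3)) == 0.5

    def test_hand_computed_four_trials(self):
        p = np.array([0.9, 0.4, 0.5, 0.2])
        c = np.array([1, 2, 1, 1])
        # hit, hit, half credit, miss
        assert accuracy(p, c) == pytest.approx((1 + 1 + 0.5 + 0) / 4)

    def test_in_sample_metrics_perfect_separation(self):
        n = 12
        rng = np.random.default_rng(0)
        d = rng.uniform(10, 170, n)
        a2 = rng.uniform(25, 80, n)
        choice = np.where(d < 90, 2, 1)  # patient below 90 days
        data = ChoiceDataset.from_arrays("ITC", np.full(n, 20.0), np.zeros(n),
                                         a2, d, choice)
        fit = fit_model(data, CBSSpec("ITC", 1), QUICK)
        m = in_sample_metrics(fit, data)
        assert 0.0 <= m["accuracy"] <= 1.0
        assert -1.0 <= m["tjurs_d"] <= 1.0


class TestRateDiagnostics:
    def test_exponential_rate_constant(self):
        f = ParametricSpec("ITC", "E", {"lnk": -4.0}).f
        for d in (1.0, 30.0, 179.0):
            assert discount_rate_at(f, d) == pytest.approx(-4.0, abs=1e-10)

    def test_hyperbolic_rate_value(self):
        f = ParametricSpec("ITC", "H", {"lnk": -4.0}).f
        expected = math.log(math.log(1 + 100 * math.exp(-4.0)) / 100)
        assert discount_rate_at(f, 100.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-4.5651, abs=1e-4)

    def test_undefined_at_one(self):
        with pytest.raises(ValueError):
            discount_rate_at(lambda d: 1.0, 10.0)
        with pytest.raises(ValueError):
            discount_rate_at(lambda d: 0.5, 0.0)

    def test_identity_weighting_neutral(self):
        for p in (0.1, 0.5, 0.9):
            assert risk_aversion_at(lambda q: q, p) == 0.0

    def test_eut_value_and_sign(self):
        f = ParametricSpec("RC", "Eut", {"alpha": 2.0}).f
        assert risk_aversion_at(f, 0.25) == pytest.approx(math.log(2), rel=1e-12)
        # q > 0 exactly where f(p) > p
        for p in (0.1, 0.4, 0.8):
            assert (risk_aversion_at(f, p) > 0) == (f(p) > p)

    @pytest.mark.parametrize("key", [k for k in recovery_parameter_sets()])
    def test_closed_forms_match_direct_evaluation(self, key):
        task, code = key
        rng = np.random.default_rng(9)
        for params in recovery_parameter_sets()[key]:
            spec = ParametricSpec(task, code, params)
            xs = rng.uniform(1.0, 179.0, 100) if task == "ITC" else rng.uniform(0.02, 0.99, 100)
            for x in xs[:25]:
                fx = float(spec.f(x))
                if task == "ITC":
                    if not 0.0 < fx < 1.0:
                        continue
                    assert discount_rate_at(spec.f, x) == pytest.approx(
                        math.log(-math.log(fx) / x), rel=1e-12)
                else:
                    if fx <= 0.0:
                        continue
                    assert risk_aversion_at(spec.f, x) == pytest.approx(
                        math.log(fx / x), rel=1e-12)


def _lsq_cbs_approx(f_target, spec, n_grid=60):
    """Least-squares 1-piece CBS approximation of a target f on [0, 1]."""
    from scipy.optimize import least_squares
    xs = np.linspace(0.005, 1.0, n_grid)
    target = f_target(xs)

    def resid(theta):
        lo = theta[4]
        th = np.clip(theta, [0, lo, 0, lo, 0], 1.0)
        return eval_curve(build_cbs_curve(th, spec), xs) - target

    theta0 = np.array([1 / 3, 0.8, 2 / 3, 0.5, 0.3])
    res = least_squares(resid, theta0, bounds=(0.0, 1.0), xtol=1e-12)
    lo = res.x[4]
    return build_cbs_curve(np.clip(res.x, [0, lo, 0, lo, 0], 1.0), spec)


class TestTrendAndSwitches:
    def test_discount_rate_trend_signs(self):
        spec = CBSSpec("ITC", 1)
        f_exp = ParametricSpec("ITC", "E", {"lnk": -4.0}).f
        f_hyp = ParametricSpec("ITC", "H", {"lnk": -3.0}).f
        trend_exp = avg_discount_rate_change(
            _lsq_cbs_approx(lambda x: f_exp(x * 180), spec), spec)
        trend_hyp = avg_discount_rate_change(
            _lsq_cbs_approx(lambda x: f_hyp(x * 180), spec), spec)
        assert trend_hyp < 0
        assert abs(trend_exp) < abs(trend_hyp)
        # concave, near-linear decline: discount rate rises with delay
        concave = build_cbs_curve(np.array([0.6, 1.0, 0.8, 0.75, 0.2]), spec)
        assert avg_discount_rate_change(concave, spec) > 0

    def test_no_switch_for_sqrt_weighting(self):
        assert count_risk_switches(lambda p: np.sqrt(p)) == 0

    def test_single_switch_for_s_shaped_weighting(self):
        f = ParametricSpec("RC", "T", {"alpha": 1.0, "gamma": 0.5}).f
        assert count_risk_switches(f) == 1

    def test_double_switch_constructed_curve(self):
        # 2-piece RC curve crossing the identity with q signs + , - , +
        spec = CBSSpec("RC", 2)
        theta = np.array([0.0, 0.45, 0.4, 0.45, 0.5, 0.45, 1.0, 0.55, 1.0])
        curve = build_cbs_curve(theta, spec)
        assert count_risk_switches(curve) == 2

    def test_dead_band_ignores_identity_riding(self):
        assert count_risk_switches(lambda p: p) == 0


class TestLOOCV:
    def _dataset(self, n=10, seed=1):
        true = ParametricSpec("ITC", "H", {"lnk": -4.0})
        design = generate_design("ITC", int(np.sqrt(n)) + 1, seed=seed)
        data = simulate_choices(design, true, sigma=1.0, seed=seed + 1)
        return data.subset(range(n))

    def test_n_holdout_predictions_and_determinism(self):
        data = self._dataset(n=10)
        spec = ParametricSpec("ITC", "E")
        r1 = loocv_evaluate(data, spec, QUICK)
        r2 = loocv_evaluate(data, spec, QUICK)
        assert len(r1["records"]) == len(data)
        assert r1["accuracy"] == r2["accuracy"]
        assert r1["tjurs_d"] == r2["tjurs_d"]

    def test_eligibility_rule(self):
        data = self._dataset(n=12)
        arr = data.arrays()
        arr["choice"][:] = 1
        arr["choice"][0] = 2  # only one option-2 trial
        lopsided = ChoiceDataset.from_arrays("ITC", arr["a1"], arr["x1"],
                                             arr["a2"], arr["x2"], arr["choice"])
        with pytest.raises(IneligibleSessionError):
            loocv_evaluate(lopsided, ParametricSpec("ITC", "E"), QUICK)

    def test_no_leakage_from_held_out_choice(self):
        data = self._dataset(n=10)
        spec = ParametricSpec("ITC", "E")
        base = loocv_evaluate(data, spec, QUICK)
        trials = list(data.trials)
        i = 4
        flipped = trials[i]
        trials[i] = type(flipped)(flipped.a1, flipped.x1, flipped.a2,
                                  flipped.x2, 3 - flipped.choice)
        perturbed = ChoiceDataset("ITC", tuple(trials))
        alt = loocv_evaluate(perturbed, spec, QUICK)
        assert alt["records"]["p_choice1"][i] == pytest.approx(
            base["records"]["p_choice1"][i], abs=1e-12)


class TestAUCJackknife:
    def test_zero_variance_gives_zero_se(self):
        assert jackknife_se(np.full(7, 0.42)) == 0.0

    def test_hand_applied_formula(self):
        v = np.array([0.50, 0.52, 0.49, 0.51, 0.53])
        n = 5
        expected = math.sqrt((n - 1) / n * np.sum((v - v.mean()) ** 2))
        assert jackknife_se(v) == pytest.approx(expected, rel=1e-12)

    def test_estimate_on_small_dataset(self):
        true = ParametricSpec("ITC", "H", {"lnk": -4.0})
        design = generate_design("ITC", 4, seed=31)
        data = simulate_choices(design, true, sigma=1.0, seed=32)
        est = auc_with_jackknife(data, CBSSpec("ITC", 1), QUICK)
        assert 0.0 <= est.auc <= 1.0
        assert est.n_trials == 16
        assert est.jackknife_se == pytest.approx(jackknife_se(est.loo_aucs), rel=1e-12)
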
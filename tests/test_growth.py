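import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from agegrowth.growth import (
    DEFAULT_L0,
    GrowthParams,
    concentrated_nll,
    fit_model,
    negative_log_likelihood,
    nll_at_sigma,
    predict_length,
    sigma_analytic,
)


class TestPredictLength:
    def test_lg3_unadjusted_length_at_birth(self):
        params = GrowthParams("LG3", 69.79, 0.444, 1.500)
        assert round(predict_length(params, 0.0), 2) == 23.69

    def test_gg3_adjusted_dc_length_at_birth(self):
        params = GrowthParams("GG3", 73.36, 0.305, 1.030)
        assert predict_length(params, 0.0) == pytest.approx(18.65, abs=0.01)

    def test_vbg3_zero_at_t0(self):
        params = GrowthParams("VBG3", 82.0, 0.17, -1.4)
        assert predict_length(params, -1.4) == pytest.approx(0.0, abs=1e-12)

    def test_vbg2_fixed_length_at_birth(self):
        params = GrowthParams("VBG2", 75.59, 0.213)
        assert params.l0_fixed == DEFAULT_L0
        assert predict_length(params, 0.0) == pytest.approx(14.50)

    def test_vectorized(self):
        params = GrowthParams("VBG3", 82.0, 0.17, -1.4)
        out = predict_length(params, np.array([0.0, 1.0, 5.0]))
        assert out.shape == (3,)
        assert (np.diff(out) > 0).all()

    @pytest.mark.parametrize(
        "params",
        [
            GrowthParams("VBG3", 82.09, 0.165, -1.988),
            GrowthParams("VBG2", 75.59, 0.213),
            GrowthParams("GG3", 73.36, 0.305, 1.030),
            GrowthParams("LG3", 69.79, 0.444, 1.500),
        ],
        ids=["VBG3", "VBG2", "GG3", "LG3"],
    )
    def test_increasing_and_asymptotic(self, params):
        ages = np.linspace(0, 40, 400)
        lengths = predict_length(params, ages)
        assert (np.diff(lengths) > 0).all()
        assert predict_length(params, 1e3) == pytest.approx(params.l_inf, rel=1e-6)

    def test_three_param_models_require_t0(self):
        with pytest.raises(ValueError):
            GrowthParams("VBG3", 82.0, 0.17)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            GrowthParams("VBG5", 82.0, 0.17, 0.0)


class TestSigma:
    def test_perfect_fit(self):
        obs = np.array([10.0, 20.0, 30.0])
        assert sigma_analytic(obs, obs) == 0.0

    def test_symmetric_log_residuals(self):
        obs = np.array([50.0, 50.0])
        pred = obs * np.exp([-0.1, 0.1])
        assert sigma_analytic(obs, pred) == pytest.approx(0.1, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            sigma_analytic([1.0, -1.0], [1.0, 1.0])

    @given(st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None)
    def test_analytic_sigma_matches_numeric_minimizer(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.uniform(20, 80, 25)
        pred = obs * np.exp(rng.normal(0, 0.1, 25))
        analytic = sigma_analytic(obs, pred)
        res = minimize_scalar(
            lambda s: nll_at_sigma(s, obs, pred), bounds=(1e-4, 2.0), method="bounded",
            options={"xatol": 1e-10},
        )
        assert analytic == pytest.approx(res.x, abs=1e-6)


class TestNll:
    def test_closed_form_sigma_one(self):
        # n=2, sigma=1: nll = ln(2 pi) + 1
        obs = np.array([50.0, 50.0])
        pred = obs * np.exp([-1.0, 1.0])
        sigma = sigma_analytic(obs, pred)
        assert sigma == pytest.approx(1.0)
        assert concentrated_nll(sigma, 2) == pytest.approx(np.log(2 * np.pi) + 1.0, abs=1e-9)

    def test_degenerate_sigma_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            concentrated_nll(0.0, 10)

    def test_identity_at_optimum(self, small_age_length):
        ages, lengths = small_age_length
        fit = fit_model("VBG3", ages, lengths)
        n = fit.n
        expected = n * (np.log(2 * np.pi) / 2 + np.log(fit.sigma) + 0.5)
        assert -fit.log_likelihood == pytest.approx(expected, abs=1e-8)

    def test_concentrated_equals_joint_minimum(self, small_age_length):
        ages, lengths = small_age_length
        fit = fit_model("VBG3", ages, lengths)
        pred = predict_length(fit.params, ages)
        res = minimize_scalar(
            lambda s: nll_at_sigma(s, lengths, pred), bounds=(1e-4, 1.0),
            method="bounded", options={"xatol": 1e-12},
        )
        assert fit.nll == pytest.approx(res.fun, abs=1e-6)

    def test_invariant_to_reordering(self, small_age_length, rng):
        ages, lengths = small_age_length
        params = GrowthParams("VBG3", 81.87, 0.168, -1.384)
        nll1, s1 = negative_log_likelihood(params, ages, lengths)
        perm = rng.permutation(len(ages))
        nll2, s2 = negative_log_likelihood(params, ages[perm], lengths[perm])
        assert nll1 == pytest.approx(nll2, abs=1e-9)
        assert s1 == pytest.approx(s2, abs=1e-12)


class TestFitModel:
    def test_noise_free_recovery(self):
        truth = GrowthParams("VBG3", 81.87, 0.168, -1.384)
        ages = np.linspace(0.5, 14, 20)
        lengths = np.asarray(predict_length(truth, ages))
        fit = fit_model("VBG3", ages, lengths)
        assert fit.params.l_inf == pytest.approx(81.87, abs=1e-4)
        assert fit.params.k == pytest.approx(0.168, abs=1e-4)
        assert fit.params.t0 == pytest.approx(-1.384, abs=1e-4)

    def test_deterministic_given_seed(self, small_age_length):
        ages, lengths = small_age_length
        f1 = fit_model("VBG3", ages, lengths, seed=5)
        f2 = fit_model("VBG3", ages, lengths, seed=5)
        assert f1.params == f2.params
        assert f1.log_likelihood == f2.log_likelihood

    def test_mean_l_inf_near_generating_truth(self):
        # replicate-mean estimate close to the generating asymptotic length
        from agegrowth.simulate import generate_age_length

        estimates = []
        for rep in range(10):
            ages, lengths = generate_age_length(1893, seed=1000 + rep)
            fit = fit_model("VBG3", ages, lengths, multistart=2)
            estimates.append(fit.params.l_inf)
        assert np.mean(estimates) == pytest.approx(81.87, rel=0.01)

    def test_wrong_model_has_higher_nll(self, small_age_length):
        ages, lengths = small_age_length  # generated from VBG3
        right = fit_model("VBG3", ages, lengths)
        wrong = fit_model("LG3", ages, lengths)
        assert wrong.converged
        assert wrong.nll > right.nll

    def test_beats_grid_search(self):
        from agegrowth.simulate import generate_age_length

        ages, lengths = generate_age_length(120, seed=3)
        fit = fit_model("VBG3", ages, lengths)
        grid_best = np.inf
        for li in np.linspace(60, 110, 30):
            for k in np.linspace(0.05, 0.6, 30):
                for t0 in np.linspace(-5, 2, 30):
                    params = GrowthParams("VBG3", li, k, t0)
                    pred = np.asarray(predict_length(params, ages))
                    if np.any(pred <= 0):
                        continue
                    nll, _ = negative_log_likelihood(params, ages, lengths)
                    grid_best = min(grid_best, nll)
        assert fit.nll <= grid_best + 1e-9

    def test_vbg2_two_free_parameters(self, small_age_length):
        ages, lengths = small_age_length
        fit = fit_model("VBG2", ages, lengths)
        assert fit.params.n_free == 2
        assert fit.params.l0_fixed == DEFAULT_L0
        assert predict_length(fit.params, 0.0) == pytest.approx(14.5)

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="at least"):
            fit_model("VBG3", [1.0, 2.0], [20.0, 30.0])

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_model("VBG3", [1.0, 2.0, 3.0, 4.0, 5.0], [20.0, -1.0, 30.0, 40.0, 50.0])
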
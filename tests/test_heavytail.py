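import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from wavetraj.heavytail import (
    MODELS,
    FitError,
    ModelFit,
    akaike_weights,
    ccdf,
    cvm_two_sample,
    fit_all,
    fit_exponential,
    fit_numeric,
    fit_power_law,
    group_test,
    sample_lengths,
)
from wavetraj.heavytail import (
    _loglik_power_law,
    _loglik_truncated_power_law,
)


class TestCcdf:
    def test_definition_on_small_sample(self):
        x, surv = ccdf([1.0, 2.0, 3.0])
        assert np.allclose(x, [1, 2, 3])
        assert np.allclose(surv, [1.0, 2 / 3, 1 / 3])

    def test_ties_share_survival(self):
        _, surv = ccdf([2.0, 2.0, 2.0])
        assert np.allclose(surv, 1.0)

    def test_nonincreasing_and_ends_at_min_mass(self, rng):
        x, surv = ccdf(rng.lognormal(0, 1, 500))
        assert np.all(np.diff(surv) <= 0)
        assert surv[0] == 1.0
        assert surv[-1] == pytest.approx(1 / 500)

    def test_within_dkw_band_of_generating_survival(self, rng):
        n = 2000
        mu, sg = -0.2, 0.8
        x, surv = ccdf(rng.lognormal(mu, sg, n))
        truth = stats.lognorm(s=sg, scale=np.exp(mu)).sf(x)
        eps = np.sqrt(np.log(2 / 0.05) / (2 * n))  # 95% DKW band
        assert np.max(np.abs(surv - truth)) < eps + 1 / n

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ccdf([])

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1e6), min_size=1, max_size=60))
    def test_survival_function_properties_hold_for_any_sample(self, values):
        x, surv = ccdf(values)
        assert np.all(np.diff(x) >= 0)
        assert np.all(np.diff(surv) <= 0)
        assert surv[0] == 1.0
        assert surv[-1] >= 1.0 / len(values)
        # idempotence under sorting: ccdf of the sorted sample is identical
        x2, surv2 = ccdf(np.sort(values))
        assert np.array_equal(x, x2) and np.array_equal(surv, surv2)


class TestClosedFormFits:
    def test_exponential_unit_rate_identity(self):
        fit = fit_exponential([1.0, 1.0, 1.0], xmin=0.0)
        assert fit.params["lambda"] == pytest.approx(1.0)

    def test_exponential_rate_recovery(self, rng):
        x = sample_lengths("exponential", {"lambda": 2.0}, 10_000, rng)
        assert fit_exponential(x).params["lambda"] == pytest.approx(2.0, abs=0.05)

    def test_exponential_analytic_equals_numeric_optimum(self, rng):
        x = sample_lengths("exponential", {"lambda": 1.3}, 2000, rng, xmin=0.2)
        lam_hat = fit_exponential(x, xmin=0.2).params["lambda"]
        res = optimize.minimize_scalar(
            lambda l: -(x.size * np.log(l) - l * np.sum(x - 0.2)),
            bounds=(1e-3, 50), method="bounded",
            options={"xatol": 1e-10},
        )
        assert lam_hat == pytest.approx(res.x, abs=1e-6)

    def test_exponential_degenerate_sample_rejected(self):
        with pytest.raises(FitError):
            fit_exponential([0.5, 0.5], xmin=0.5)

    def test_power_law_all_values_at_e_times_xmin_gives_two(self):
        xmin = 0.3
        fit = fit_power_law(np.full(50, np.e * xmin), xmin=xmin)
        assert fit.params["gamma"] == pytest.approx(2.0)

    def test_power_law_exponent_recovery(self, rng):
        x = sample_lengths("power_law", {"gamma": 2.5}, 10_000, rng, xmin=0.1)
        assert fit_power_law(x, xmin=0.1).params["gamma"] == pytest.approx(2.5, abs=0.05)

    def test_power_law_analytic_equals_numeric_optimum(self, rng):
        x = sample_lengths("power_law", {"gamma": 2.2}, 2000, rng, xmin=0.1)
        g_hat = fit_power_law(x, xmin=0.1).params["gamma"]
        res = optimize.minimize_scalar(
            lambda g: -_loglik_power_law(x, 0.1, g), bounds=(1.01, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert g_hat == pytest.approx(res.x, abs=1e-6)


class TestNumericFits:
    def test_lognormal_matches_scipy_closed_form_fit(self, rng):
        # with xmin at the sample minimum the truncation correction is tiny and
        # the numeric MLE must agree with scipy's untruncated lognormal MLE
        x = rng.lognormal(-0.2, 0.8, 4000)
        fit = fit_numeric(x, "lognormal")
        shape, _, scale = stats.lognorm.fit(x, floc=0)
        assert fit.params["mu"] == pytest.approx(np.log(scale), abs=5e-3)
        assert fit.params["sigma"] == pytest.approx(shape, abs=5e-3)

    @pytest.mark.parametrize(
        "model,params,xmin,tol",
        [
            ("lognormal", {"mu": -0.193, "sigma": 0.804}, 0.0, 0.06),
            ("stretched_exponential", {"lambda": 0.84, "beta": 1.037}, 0.0, 0.09),
            ("truncated_power_law", {"gamma": 1.5, "lambda": 0.5}, 0.1, 0.25),
        ],
    )
    def test_parameter_recovery_at_moderate_n(self, rng, model, params, xmin, tol):
        x = sample_lengths(model, params, 3000, rng, xmin=xmin)
        fit = fit_numeric(x, model, xmin=xmin if xmin > 0 else None)
        for name, true in params.items():
            assert fit.params[name] == pytest.approx(true, abs=tol)

    @pytest.mark.parametrize(
        "model,params,xmin",
        [
            ("lognormal", {"mu": -0.193, "sigma": 0.804}, 0.0),
            ("stretched_exponential", {"lambda": 0.84, "beta": 1.037}, 0.0),
            ("truncated_power_law", {"gamma": 1.5, "lambda": 0.5}, 0.1),
        ],
    )
    def test_fitted_loglik_at_least_that_of_true_parameters(self, rng, model, params, xmin):
        from wavetraj.heavytail import (
            _loglik_lognormal,
            _loglik_stretched_exponential,
        )

        x = sample_lengths(model, params, 2000, rng, xmin=xmin)
        fit = fit_numeric(x, model, xmin=xmin if xmin > 0 else None)
        if model == "lognormal":
            ll_true = _loglik_lognormal(x, fit.xmin, params["mu"], params["sigma"])
        elif model == "stretched_exponential":
            ll_true = _loglik_stretched_exponential(x, fit.xmin, params["lambda"], params["beta"])
        else:
            ll_true = _loglik_truncated_power_law(x, fit.xmin, params["gamma"], params["lambda"])
        assert fit.loglik >= ll_true - 1e-6

    def test_truncated_power_law_degenerates_to_power_law_as_cutoff_vanishes(self, rng):
        x = sample_lengths("power_law", {"gamma": 2.0}, 500, rng, xmin=0.1)
        gamma = 2.0
        ll_pl = _loglik_power_law(x, 0.1, gamma)
        ll_tpl = _loglik_truncated_power_law(x, 0.1, gamma, 1e-9)
        assert ll_tpl == pytest.approx(ll_pl, abs=1e-3)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_numeric(rng.lognormal(0, 1, 5), "lognormal")


class TestAkaikeWeights:
    def _fit(self, model, loglik, n=100, xmin=0.1):
        params = {
            "lognormal": {"mu": 0.0, "sigma": 1.0},
            "power_law": {"gamma": 2.0},
            "exponential": {"lambda": 1.0},
        }[model]
        return ModelFit(model=model, params=params, xmin=xmin, loglik=loglik, n=n)

    def test_equal_aics_give_uniform_weights(self):
        # two 2-parameter... use models with equal k so equal loglik => equal AIC
        fits = [self._fit("power_law", -50.0), self._fit("exponential", -50.0)]
        comp = akaike_weights(fits)
        assert comp.weights["power_law"] == pytest.approx(0.5)

    def test_delta_aic_of_two_maps_to_known_weights(self):
        # delta AIC = 2 <=> weights 1/(1+e^-1), e^-1/(1+e^-1) = 0.7311, 0.2689
        fits = [self._fit("power_law", -50.0), self._fit("exponential", -51.0)]
        comp = akaike_weights(fits)
        assert comp.weights["power_law"] == pytest.approx(0.7311, abs=5e-4)
        assert comp.weights["exponential"] == pytest.approx(0.2689, abs=5e-4)
        assert comp.winner == "power_law"

    def test_weights_sum_to_one(self, rng):
        x = sample_lengths("lognormal", {"mu": 0.0, "sigma": 1.0}, 500, rng)
        comp = akaike_weights(fit_all(x))
        assert sum(comp.weights.values()) == pytest.approx(1.0, abs=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=2, max_size=5))
    def test_weights_normalized_and_winner_maximal_for_any_logliks(self, logliks):
        models = ["lognormal", "power_law", "truncated_power_law",
                  "stretched_exponential", "exponential"][: len(logliks)]
        params = {"lognormal": {"mu": 0.0, "sigma": 1.0}, "power_law": {"gamma": 2.0},
                  "truncated_power_law": {"gamma": 2.0, "lambda": 1.0},
                  "stretched_exponential": {"lambda": 1.0, "beta": 1.0},
                  "exponential": {"lambda": 1.0}}
        fits = [ModelFit(model=m, params=params[m], xmin=0.1, loglik=ll, n=50)
                for m, ll in zip(models, logliks)]
        comp = akaike_weights(fits)
        w = comp.weights
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in w.values())
        assert w[comp.winner] == max(w.values())

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([self._fit("power_law", -50.0, n=100),
                            self._fit("exponential", -50.0, n=101)])

    @pytest.mark.parametrize(
        "model,params,xmin",
        [
            ("lognormal", {"mu": -0.193, "sigma": 0.804}, 0.0),
            ("power_law", {"gamma": 2.5}, 0.1),
            ("truncated_power_law", {"gamma": 1.5, "lambda": 0.5}, 0.1),
            ("stretched_exponential", {"lambda": 1.0, "beta": 0.7}, 0.0),
            ("exponential", {"lambda": 1.0}, 0.0),
        ],
    )
    def test_generating_model_wins_model_selection(self, model, params, xmin):
        rng = np.random.default_rng(0)
        x = sample_lengths(model, params, 2000, rng, xmin=xmin)
        comp = akaike_weights(fit_all(x, xmin=xmin if xmin > 0 else None))
        assert comp.winner == model


class TestSamplers:
    @pytest.mark.parametrize("model,params,xmin", [
        ("lognormal", {"mu": 0.0, "sigma": 0.8}, 0.5),
        ("power_law", {"gamma": 2.5}, 0.2),
        ("truncated_power_law", {"gamma": 1.5, "lambda": 1.0}, 0.2),
        ("stretched_exponential", {"lambda": 1.0, "beta": 0.9}, 0.3),
        ("exponential", {"lambda": 2.0}, 0.4),
    ])
    def test_respect_support_and_determinism(self, model, params, xmin):
        x1 = sample_lengths(model, params, 500, np.random.default_rng(5), xmin=xmin)
        x2 = sample_lengths(model, params, 500, np.random.default_rng(5), xmin=xmin)
        assert np.all(x1 >= xmin)
        assert np.array_equal(x1, x2)


class TestTwoSampleTests:
    def test_cvm_identical_samples_not_rejected(self, rng):
        a = rng.lognormal(0, 1, 200)
        res = cvm_two_sample(a, a)
        assert res.pvalue > 0.5

    def test_cvm_detects_shift(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(2, 1, 1000)
        assert cvm_two_sample(a, b).pvalue < 0.01

    def test_cvm_invariant_under_common_monotone_rescaling(self, rng):
        a = rng.lognormal(0, 1, 150)
        b = rng.lognormal(0.3, 1, 150)
        s1 = cvm_two_sample(a, b).statistic
        s2 = cvm_two_sample(a**3, b**3).statistic
        assert s1 == pytest.approx(s2)

    def test_cvm_permutation_p_agrees_with_asymptotic(self, rng):
        a = rng.normal(0, 1, 80)
        b = rng.normal(0.5, 1, 80)
        p_asym = cvm_two_sample(a, b).pvalue
        p_perm = cvm_two_sample(a, b, method="permutation", n_perm=400, rng=1).pvalue
        assert abs(p_asym - p_perm) < 0.1

    def test_paired_t_on_identical_vectors(self):
        res = group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_mann_whitney_flags_separated_groups(self):
        a = np.arange(8, dtype=float)
        b = np.arange(10, 18, dtype=float)
        assert group_test(a, b).pvalue < 0.01

    def test_unpaired_test_invariant_to_within_group_order(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=15)
        r1 = group_test(a, b)
        r2 = group_test(np.sort(a), b[::-1])
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.pvalue == pytest.approx(r2.pvalue)

    def test_paired_with_unmatched_ids_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            group_test([1.0, 2.0], [1.0, 2.0], paired=True,
                       ids_a=["c1", "c2"], ids_b=["c1", "c3"])
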
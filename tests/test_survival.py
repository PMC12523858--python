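"""Parametric survival families: closed forms, invariants, ML fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines import LogLogisticFitter, LogNormalFitter, WeibullFitter
from scipy.integrate import quad

import psmcea as P
from psmcea.survival import FitResult

EXAMPLE_MODELS = {
    "exponential": (0.1,),
    "weibull": (1.4, 12.0),
    "gamma": (1.8, 7.0),
    "lognormal": (2.538, 0.947),
    "loglogistic": (2.004, 13.331),
    "gompertz": (0.05, 0.04),
    "gengamma": (2.2, 0.7, 0.8),
}


class TestSurvivalFunctions:
    @pytest.mark.parametrize("family,params", EXAMPLE_MODELS.items())
    def test_survival_starts_at_one(self, family, params):
        m = P.ParametricSurvival(family, params)
        assert P.survival_probability(m, 0.0) == pytest.approx(1.0)

    def test_loglogistic_median_equals_scale(self):
        m = P.ParametricSurvival("loglogistic", (2.004, 13.331))
        assert P.survival_probability(m, 13.331) == pytest.approx(0.5)
        assert m.median() == pytest.approx(13.331)

    def test_lognormal_median_is_exp_mu(self):
        m = P.ParametricSurvival("lognormal", (2.538, 0.947))
        assert P.survival_probability(m, np.exp(2.538)) == pytest.approx(0.5)

    def test_exponential_closed_form(self):
        m = P.ParametricSurvival("exponential", (0.1,))
        assert P.survival_probability(m, 10.0) == pytest.approx(np.exp(-1.0))

    @pytest.mark.parametrize("family,params", EXAMPLE_MODELS.items())
    def test_survival_monotone_nonincreasing(self, family, params):
        m = P.ParametricSurvival(family, params)
        s = m.sf(np.linspace(0.0, 480.0, 10_000))
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0.0) & (s <= 1.0))

    @pytest.mark.parametrize("family,params", EXAMPLE_MODELS.items())
    def test_density_integrates_to_one(self, family, params):
        m = P.ParametricSurvival(family, params)
        total, _ = quad(lambda t: float(m.pdf(t)), 0.0, 2000.0, limit=200)
        assert total + float(m.sf(2000.0)) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("family,params", EXAMPLE_MODELS.items())
    def test_quantile_inverts_survival(self, family, params):
        m = P.ParametricSurvival(family, params)
        for q in (0.1, 0.5, 0.9):
            assert 1.0 - float(m.sf(m.ppf(q))) == pytest.approx(q, abs=1e-8)

    def test_negative_gompertz_shape_is_improper(self):
        m = P.ParametricSurvival("gompertz", (-0.08, 0.05))
        assert m.improper
        # survival plateaus at the cure fraction exp(rate/shape)
        assert float(m.sf(1e6)) == pytest.approx(np.exp(0.05 / -0.08), rel=1e-6)

    def test_negative_time_rejected(self):
        m = P.ParametricSurvival("weibull", (1.0, 10.0))
        with pytest.raises(ValueError):
            m.sf(-1.0)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            P.ParametricSurvival("loglogistic", (2.0, 0.0))
        with pytest.raises(ValueError):
            P.ParametricSurvival("lognormal", (1.0, -0.5))

    @given(
        shape=st.floats(0.5, 5.0), scale=st.floats(1.0, 50.0),
        t1=st.floats(0.0, 200.0), t2=st.floats(0.0, 200.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_loglogistic_ordering_property(self, shape, scale, t1, t2):
        m = P.ParametricSurvival("loglogistic", (shape, scale))
        lo, hi = sorted((t1, t2))
        assert float(m.sf(hi)) <= float(m.sf(lo)) + 1e-12


class TestFitting:
    def test_exponential_mle_matches_closed_form(self, loglogistic_sample):
        _, ipd = loglogistic_sample
        fit = P.fit_parametric(ipd, "exponential")
        rate_closed = ipd["event"].sum() / ipd["time_months"].sum()
        assert fit.model.params[0] == pytest.approx(rate_closed, rel=1e-4)

    @pytest.mark.parametrize("family,params", EXAMPLE_MODELS.items())
    def test_parameter_recovery_within_3_se(self, family, params):
        model = P.ParametricSurvival(family, params)
        seed = 100 + P.FAMILIES.index(family)
        ipd = P.simulate_ipd(
            P.SimulationRecipe(model=model, n=10_000, arm="x", seed=seed)
        )
        fit = P.fit_parametric(ipd, family)
        assert fit.converged
        for est, truth, se in zip(fit.model.params, params, fit.param_se):
            assert abs(est - truth) <= 3.0 * se, (family, est, truth, se)

    def test_censored_recovery_loglogistic(self, loglogistic_sample):
        model, ipd = loglogistic_sample
        fit = P.fit_parametric(ipd, "loglogistic")
        for est, truth, se in zip(fit.model.params, model.params, fit.param_se):
            assert abs(est - truth) <= 3.0 * se

    @pytest.mark.parametrize(
        "family,fitter,attrs",
        [
            ("weibull", WeibullFitter, ("rho_", "lambda_")),
            ("lognormal", LogNormalFitter, ("mu_", "sigma_")),
            ("loglogistic", LogLogisticFitter, ("beta_", "alpha_")),
        ],
    )
    def test_agrees_with_lifelines(self, loglogistic_sample, family, fitter, attrs):
        """Independent MLE route (lifelines) reproduces our estimates."""
        _, ipd = loglogistic_sample
        ours = P.fit_parametric(ipd, family)
        lf = fitter().fit(ipd["time_months"], ipd["event"])
        theirs = tuple(getattr(lf, a) for a in attrs)
        for a, b in zip(ours.model.params, theirs):
            assert a == pytest.approx(b, rel=1e-3)
        assert ours.loglik == pytest.approx(lf.log_likelihood_, rel=1e-6)

    def test_no_events_rejected(self):
        ipd = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            P.fit_parametric(ipd, "exponential")


class TestInformationCriteria:
    def test_aic_bic_identities(self, loglogistic_sample):
        _, ipd = loglogistic_sample
        fit = P.fit_parametric(ipd, "weibull")
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.bic == pytest.approx(-2 * fit.loglik + fit.n_params * np.log(fit.n_obs))
        assert np.all(fit.param_se >= 0)

    def test_single_fit_single_row(self, loglogistic_sample):
        _, ipd = loglogistic_sample
        table = P.information_criteria([P.fit_parametric(ipd, "exponential")])
        assert len(table) == 1

    def test_aic_penalty_breaks_loglik_tie(self):
        m1 = P.ParametricSurvival("exponential", (0.1,))
        m2 = P.ParametricSurvival("weibull", (1.0, 10.0))
        f1 = FitResult(model=m1, loglik=-100.0, n_params=1, n_obs=50, param_se=np.zeros(1))
        f2 = FitResult(model=m2, loglik=-100.0, n_params=2, n_obs=50, param_se=np.zeros(2))
        table = P.information_criteria([f2, f1])
        assert table.iloc[0]["family"] == "exponential"

    def test_differing_nobs_rejected(self):
        m = P.ParametricSurvival("exponential", (0.1,))
        f1 = FitResult(model=m, loglik=-10, n_params=1, n_obs=50, param_se=np.zeros(1))
        f2 = FitResult(model=m, loglik=-10, n_params=1, n_obs=60, param_se=np.zeros(1))
        with pytest.raises(ValueError):
            P.information_criteria([f1, f2])

    def test_true_family_ranks_near_top(self, loglogistic_sample):
        _, ipd = loglogistic_sample
        table = P.information_criteria(
            [P.fit_parametric(ipd, f) for f in P.FAMILIES]
        )
        assert "loglogistic" in set(table["family"].head(2))
        # Weibull nests the exponential: its maximized likelihood dominates
        aic = table.set_index("family")["aic"]
        assert aic["weibull"] <= aic["exponential"] + 2.0 + 1e-6
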
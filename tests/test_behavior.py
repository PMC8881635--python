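"""Subjective-value model, likelihood, fitting and slope estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import moralsv as m
from moralsv import behavior
from moralsv.data import FINANCIAL, MORAL
from moralsv.errors import ValidationError

from conftest import make_dataset


class TestSubjectiveValue:
    @pytest.mark.parametrize(
        "func,magnitude,k,rating,expected",
        [
            (m.sv_financial, 120.0, 0.0, 100.0, 120.0),  # no discounting
            (m.sv_financial, 100.0, 0.01, 100.0, 50.0),  # divisor exactly 2
            (m.sv_financial, 60.0, 0.043, 100.0, 60.0 / 5.3),  # steepest printed K_f
            (m.sv_moral, 10.0, 0.0, 100.0, 10.0),
            (m.sv_moral, 1.0, 3.3, 0.0, 1.0),  # clean record: no discount
            (m.sv_moral, 10.0, 7.08, 1.0, 10.0 / 8.08),  # steepest printed K_m
        ],
    )
    def test_hyperbolic_values(self, func, magnitude, k, rating, expected):
        assert func(magnitude, k, rating) == pytest.approx(expected, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            m.sv_financial(-1.0, 0.01, 10.0)
        with pytest.raises(ValidationError):
            m.sv_moral(5.0, -0.1, 10.0)
        with pytest.raises(ValidationError):
            m.sv_financial(5.0, 0.1, -10.0)

    @given(
        magnitude=st.floats(1.0, 120.0),
        k=st.floats(1e-5, 10.0),
        rating=st.floats(0.0, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_financial_and_moral_models_are_isomorphic(self, magnitude, k, rating):
        """The two tasks' value models are the same function of their inputs."""
        assert m.sv_financial(magnitude, k, rating) == m.sv_moral(magnitude, k, rating)

    @given(
        magnitude=st.floats(1.0, 120.0),
        k=st.floats(1e-4, 5.0),
        rating=st.floats(1.0, 100.0),
        bump=st.floats(0.1, 2.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotonicity(self, magnitude, k, rating, bump):
        """SV strictly decreases in K and rating, increases in magnitude."""
        base = m.sv_financial(magnitude, k, rating)
        assert m.sv_financial(magnitude, k * (1 + bump), rating) < base
        assert m.sv_financial(magnitude, k, rating * (1 + bump)) < base
        assert m.sv_financial(magnitude * (1 + bump), k, rating) > base


class TestChoiceLoglik:
    def test_indifferent_subject(self):
        ds = make_dataset(FINANCIAL, [60, 80, 100], [50, 50, 50], [1, 0, 1])
        n = ds.n_trials
        assert m.choice_loglik(0.01, 0.0, ds) == pytest.approx(n * math.log(0.5))

    def test_zero_sv_difference(self):
        # magnitude 40 at rating 100 with K = 0.01 has SV exactly 20 = reference
        ds = make_dataset(FINANCIAL, [40.0], [100.0], [True])
        assert m.choice_loglik(0.01, 3.0, ds) == pytest.approx(math.log(0.5))

    def test_four_trial_hand_computation(self):
        """Likelihood equals a spreadsheet-style per-trial computation."""
        k, beta = 0.01, 0.1
        ds = make_dataset(
            FINANCIAL,
            magnitudes=[100.0, 40.0, 30.0, 120.0],
            perceived=[50.0, 100.0, 100.0, 0.0],
            chose=[True, False, False, False],
        )
        svs = [100.0 / 1.5, 40.0 / 2.0, 30.0 / 2.0, 120.0 / 1.0]
        probs = [1.0 / (1.0 + math.exp(-beta * (sv - 20.0))) for sv in svs]
        expected = (
            math.log(probs[0])
            + math.log(1 - probs[1])
            + math.log(1 - probs[2])
            + math.log(1 - probs[3])
        )
        assert m.choice_loglik(k, beta, ds) == pytest.approx(expected, rel=1e-12)

    def test_loglik_is_finite_even_for_certain_wrong_choices(self):
        ds = make_dataset(FINANCIAL, [120.0], [0.0], [False])  # dSV = 100, rejected
        ll = m.choice_loglik(1e-4, 100.0, ds)
        assert np.isfinite(ll)
        assert ll <= math.log(1e-12) * 0.9  # clipped, not -inf

    def test_invalid_parameters_rejected(self):
        ds = make_dataset(FINANCIAL, [60.0], [50.0], [True])
        with pytest.raises(ValidationError):
            m.choice_loglik(float("nan"), 1.0, ds)
        with pytest.raises(ValidationError):
            m.choice_loglik(-0.1, 1.0, ds)


class TestFitSubject:
    def test_recovers_known_parameters(self, agent, financial_design):
        design = m.build_design(FINANCIAL, repeats=10)  # 600 trials
        ds = m.simulate_choices(agent, design, seed=3)
        fit = m.fit_subject(ds, seed=0)
        assert fit.converged
        assert fit.k_hat == pytest.approx(agent.k_f, rel=0.2)

    def test_deterministic_given_seed(self, financial_dataset):
        a = m.fit_subject(financial_dataset, seed=5)
        b = m.fit_subject(financial_dataset, seed=5)
        assert (a.k_hat, a.beta_hat, a.loglik) == (b.k_hat, b.beta_hat, b.loglik)

    def test_all_same_choices_flagged_not_raised(self):
        ds = make_dataset(FINANCIAL, [60, 80, 100, 120], [50, 50, 80, 80], [1, 1, 1, 1])
        with pytest.warns(UserWarning, match="not identifiable"):
            fit = m.fit_subject(ds)
        assert not fit.identifiable
        assert fit.k_hat == pytest.approx(behavior.DEFAULT_K_BOUNDS[0], rel=1.0)

    def test_matches_grid_search(self, agent):
        """Optimizer finds the same optimum as an exhaustive log-grid search."""
        ds = m.simulate_choices(agent, m.build_design(FINANCIAL), seed=21)
        fit = m.fit_subject(ds, seed=0)
        kg, bg, llg = behavior.grid_search_fit(ds, n_k=100, n_beta=100)
        cell = math.log(20.0 / 1e-6) / 99
        assert (
            abs(math.log(fit.k_hat) - math.log(kg)) <= cell
            or fit.loglik >= llg - 1e-4
        )
        assert fit.loglik >= llg - 1e-4

    def test_invalid_bounds_rejected(self, financial_dataset):
        with pytest.raises(ValidationError):
            m.fit_subject(financial_dataset, k_bounds=(0.1, 0.1))


class TestDiscountCurveR2:
    def test_perfect_deterministic_agent(self, financial_design):
        """A noiseless agent whose cells the model predicts exactly gives R2 = 1."""
        # k chosen so no design cell sits exactly at indifference (an exact
        # tie makes the simulated choice a coin flip the model cannot match)
        agent = m.AgentParams(
            subject_id="det",
            k_f=0.019,
            k_m=1.0,
            beta_f=1e6,
            beta_m=1e6,
            perception=m.PerceptionRatings.default(),
            rt_intercept=1200.0,
            rt_slope_financial=3.0,
            rt_slope_moral=40.0,
            rt_sd=50.0,
        )
        ds = m.simulate_choices(agent, financial_design, seed=1)
        r2 = m.discount_curve_r2(agent.k_f, 200.0, ds)
        assert r2 == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_constant_proportions(self):
        ds = make_dataset(
            FINANCIAL, [40.0, 40.0], [100.0, 100.0], [True, False], levels=[1, 1]
        )
        # single cell at 50% with prediction 0.5: zero variance -> undefined
        assert math.isnan(m.discount_curve_r2(0.025, 1.0, ds))

    def test_indifference_variant_high_for_low_noise(self, financial_design):
        agent = m.sample_agent(
            m.PopulationConfig(beta_f_range=(8.0, 9.0), k_f_range=(0.005, 0.02)), seed=3
        )
        ds = m.simulate_choices(agent, m.build_design(FINANCIAL, repeats=4), seed=9)
        r2 = m.discount_curve_r2(agent.k_f, agent.beta_f, ds, method="indifference")
        assert r2 > 0.8


class TestSlopes:
    def test_rt_slope_equals_closed_form_ols(self):
        """Six-point linear RT data: slope equals the textbook least-squares slope."""
        sv = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        rt = np.array([1500.0, 1400.0, 1350.0, 1280.0, 1150.0, 1100.0])
        ds = make_dataset(
            FINANCIAL, sv, np.zeros(6), [1, 1, 1, 0, 0, 0], rt=rt, sv=sv
        )
        z = (sv - sv.mean()) / sv.std()
        expected = np.sum((z - z.mean()) * (rt - rt.mean())) / np.sum((z - z.mean()) ** 2)
        res = m.rt_slope(ds)
        assert res.kind == "rt_linear"
        assert res.beta1 == pytest.approx(expected, rel=1e-9)

    def test_choice_slope_null_when_choices_ignore_sv(self):
        rng = np.random.default_rng(4)
        sv = rng.uniform(20, 120, 400)
        ds = make_dataset(
            FINANCIAL, sv, np.zeros(400), rng.random(400) < 0.5, sv=sv
        )
        res = m.choice_slope(ds)
        assert abs(res.beta1) < 3.0 * (1.0 / np.sqrt(400) * 2.0)

    def test_choice_slope_positive_under_strong_discounting(self, financial_dataset):
        assert m.choice_slope(financial_dataset).beta1 > 0

    def test_choice_slope_close_to_unpenalized_mle(self):
        """Firth estimate agrees with the plain MLE away from separation."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        z = rng.normal(size=400)
        y = rng.random(400) < 1.0 / (1.0 + np.exp(-(0.2 + 1.5 * z)))
        ds = make_dataset(FINANCIAL, np.full(400, 60.0), np.zeros(400), y, sv=z)
        firth = m.choice_slope(ds).beta1
        zz = (z - z.mean()) / z.std()
        mle = sm.Logit(y.astype(float), sm.add_constant(zz)).fit(disp=0).params[1]
        assert firth == pytest.approx(mle, rel=0.05)

    def test_zero_sv_variance_rejected(self):
        ds = make_dataset(FINANCIAL, [60.0, 60.0], [50.0, 50.0], [1, 0], sv=[30.0, 30.0])
        with pytest.raises(ValidationError):
            m.choice_slope(ds)
        with pytest.raises(ValidationError):
            m.rt_slope(ds)
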
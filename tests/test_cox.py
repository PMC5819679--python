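"""Partial-likelihood engine: oracle agreement, inference, criterion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bmtsim as b
from bmtsim.cohort import Cohort
from bmtsim.cox import PHI_975, ConvergenceError, CoxData, model_aic
from conftest import brute_force_partial_loglik


def tiny_cohort(rng, n):
    return Cohort(
        treatment=(rng.random(n) < 0.5).astype(float),
        biomarker=rng.standard_normal(n),
        covariates=rng.standard_normal((n, 2)),
        time=rng.permutation(np.linspace(0.5, 4.0, n)),  # distinct times
        event=np.ones(n, dtype=np.int8),
    )


class TestPartialLikelihoodOracle:
    def test_null_loglik_matches_hand_computed_risk_sets(self):
        # 3 subjects, all events, distinct times: risk sets of sizes 3, 2, 1
        # give a null partial log-likelihood of -ln 6
        cohort = Cohort(
            treatment=np.array([0.0, 1.0, 0.0]),
            biomarker=np.zeros(3),
            covariates=np.zeros((3, 1)),
            time=np.array([1.0, 2.0, 3.0]),
            event=np.ones(3, dtype=np.int8),
        )
        data = b.cohort_design(cohort)
        assert data.null_loglik() == pytest.approx(-math.log(6), abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_loglik_matches_brute_force_on_small_cohorts(self, n):
        rng = np.random.default_rng(n)
        cohort = tiny_cohort(rng, n)
        data = b.cohort_design(cohort)
        X = np.column_stack([cohort.biomarker, cohort.covariates[:, 0]])
        for beta in ([0.0, 0.0], [0.3, -0.2], [1.5, 0.8], [-2.0, 0.1]):
            oracle = brute_force_partial_loglik(cohort.time, cohort.event, X, beta)
            ours = data.partial_loglik_at(["biomarker", "x1"], np.asarray(beta))
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_fitted_loglik_matches_brute_force_when_converged(self):
        rng = np.random.default_rng(8)
        cohort = tiny_cohort(rng, 8)
        data = b.cohort_design(cohort)
        fit = data.fit(["biomarker"])
        assert fit.converged
        oracle = brute_force_partial_loglik(
            cohort.time, cohort.event, cohort.biomarker[:, None], fit.coefficients
        )
        assert fit.partial_loglik == pytest.approx(oracle, abs=1e-8)

    def test_fitted_loglik_not_below_null(self, default_cohort):
        cohort, *_ = default_cohort
        data = b.cohort_design(cohort)
        fit = data.fit(["treatment", "biomarker", "treatment:biomarker"])
        assert fit.partial_loglik >= data.null_loglik()


class TestAgainstLifelines:
    def test_coefficients_covariance_loglik_agree(self, default_cohort):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        cohort, *_ = default_cohort
        names = ["treatment", "biomarker", "treatment:biomarker", "x1", "x2", "x3"]
        fit = b.fit_cox(cohort, names)
        df = pd.DataFrame(
            {
                "time": cohort.time,
                "event": cohort.event,
                "treatment": cohort.treatment,
                "biomarker": cohort.biomarker,
                "inter": cohort.treatment * cohort.biomarker,
                "x1": cohort.covariates[:, 0],
                "x2": cohort.covariates[:, 1],
                "x3": cohort.covariates[:, 2],
            }
        )
        cph = lifelines.CoxPHFitter().fit(df, "time", "event")
        assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-4)
        assert np.allclose(
            np.sqrt(np.diag(fit.covariance)), cph.standard_errors_.values, atol=1e-5
        )
        assert fit.partial_loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)


class TestFitBehaviour:
    def test_large_n_parameter_recovery(self):
        cohort, spec, coeffs = b.make_fixture("known_beta_cohort", seed=11)
        names = ["treatment", "biomarker", "treatment:biomarker"] + [
            f"x{j+1}" for j in range(spec.k)
        ]
        fit = b.fit_cox(cohort, names)
        assert fit.converged
        truth = np.concatenate(
            [[spec.beta_t, spec.beta_b, spec.beta_interaction], coeffs.values]
        )
        se = np.sqrt(np.diag(fit.covariance))
        assert np.all(np.abs(fit.coefficients - truth) < 3 * se)

    def test_fit_is_deterministic(self, default_cohort):
        cohort, *_ = default_cohort
        a = b.fit_cox(cohort, ["treatment", "biomarker", "treatment:biomarker"])
        c = b.fit_cox(cohort, ["treatment", "biomarker", "treatment:biomarker"])
        assert np.array_equal(a.coefficients, c.coefficients)
        assert a.partial_loglik == c.partial_loglik

    def test_covariance_symmetric_when_converged(self, default_cohort):
        cohort, *_ = default_cohort
        fit = b.fit_cox(cohort, ["treatment", "biomarker", "treatment:biomarker", "x1"])
        assert fit.converged
        assert np.allclose(fit.covariance, fit.covariance.T, atol=1e-10)
        assert np.all(np.diag(fit.covariance) > 0)
        assert fit.n_parameters == 4

    def test_monotone_likelihood_flagged_not_raised(self):
        # covariate perfectly ordered with time -> divergent coefficient
        n = 12
        time = np.linspace(0.1, 3.0, n)
        cohort = Cohort(
            treatment=np.tile([0.0, 1.0], n // 2),
            biomarker=np.zeros(n) + np.linspace(-0.1, 0.1, n),
            covariates=(-time).reshape(-1, 1),
            time=time,
            event=np.ones(n, dtype=np.int8),
        )
        fit = b.cohort_design(cohort).fit(["x1"])
        assert not fit.converged

    def test_error_on_empty_set_zero_events_constant_column(self, default_cohort):
        cohort, *_ = default_cohort
        with pytest.raises(ValueError):
            b.fit_cox(cohort, [])
        with pytest.raises(ValueError, match="constant"):
            data = b.cohort_design(cohort)
            bad = CoxData(
                cohort.time,
                cohort.event,
                np.ones((cohort.n, 1)),
                ["const"],
            )
            bad.fit(["const"])
        with pytest.raises(ValueError, match="events"):
            CoxData(
                cohort.time,
                np.zeros(cohort.n, dtype=int),
                np.ones((cohort.n, 1)),
                ["x"],
            )


class TestInteractionInference:
    def make_fit(self, estimate, variance, converged=True):
        return b.FitResult(
            covariate_names=("treatment", "biomarker", "treatment:biomarker"),
            coefficients=np.array([0.1, 0.2, estimate]),
            covariance=np.diag([0.01, 0.01, variance]),
            partial_loglik=-100.0,
            converged=converged,
            n_events=300,
            n_parameters=3,
        )

    def test_null_estimate_unit_variance(self):
        inf = b.interaction_inference(self.make_fit(0.0, 1.0))
        assert inf.p_value == pytest.approx(1.0)
        assert inf.ci_low == pytest.approx(-1.959964)
        assert inf.ci_high == pytest.approx(1.959964)

    def test_ci_from_estimate_and_variance(self):
        inf = b.interaction_inference(self.make_fit(0.285, 0.01))
        assert inf.ci_low == pytest.approx(0.285 - 1.959964 * 0.1, abs=1e-9)
        assert inf.ci_high == pytest.approx(0.285 + 1.959964 * 0.1, abs=1e-9)

    def test_boundary_estimate_gives_five_percent(self):
        variance = 0.04
        inf = b.interaction_inference(self.make_fit(PHI_975 * math.sqrt(variance), variance))
        assert inf.p_value == pytest.approx(0.05, abs=1e-6)

    def test_nonconverged_fit_signals_exclusion(self):
        with pytest.raises(ConvergenceError):
            b.interaction_inference(self.make_fit(0.0, 1.0, converged=False))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        estimate=st.floats(-3, 3),
        variance=st.floats(1e-4, 4.0),
    )
    def test_invariants_hold_for_any_estimate(self, estimate, variance):
        inf = b.interaction_inference(self.make_fit(estimate, variance))
        assert 0.0 <= inf.p_value <= 1.0
        assert inf.ci_low <= inf.estimate <= inf.ci_high


class TestModelAic:
    def test_criterion_formula(self):
        fit = b.FitResult(("x",), np.zeros(1), np.eye(1), -100.0, True, 10, 3)
        assert model_aic(fit) == pytest.approx(-206.0)
        zero = b.FitResult((), np.zeros(0), np.zeros((0, 0)), 0.0, True, 10, 0)
        assert model_aic(zero) == 0.0

    def test_one_parameter_worth_one_loglik_unit(self):
        base = b.FitResult(("x",), np.zeros(1), np.eye(1), -100.0, True, 10, 1)
        bigger = b.FitResult(("x", "y"), np.zeros(2), np.eye(2), -98.99, True, 10, 2)
        assert model_aic(bigger) - model_aic(base) == pytest.approx(0.02)

    def test_requires_convergence(self):
        fit = b.FitResult(("x",), np.zeros(1), np.eye(1), -100.0, False, 10, 1)
        with pytest.raises(ConvergenceError):
            model_aic(fit)
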
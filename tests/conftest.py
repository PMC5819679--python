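import numpy as np
import pytest

import bmtsim as b
from bmtsim.scenarios import calibration_seed, run_seed

MASTER_SEED = 20180220


def brute_force_partial_loglik(time, event, X, beta):
    """Independent risk-set evaluation of the partial log-likelihood."""
    time = np.asarray(time, float)
    eta = np.asarray(X, float) @ np.asarray(beta, float)
    ll = 0.0
    for i in np.flatnonzero(np.asarray(event).astype(bool)):
        risk = time >= time[i]
        ll += eta[i] - np.log(np.exp(eta[risk]).sum())
    return ll


def default_spec(**overrides) -> b.ScenarioSpec:
    base = dict(
        k=12,
        censoring_band="low",
        interaction="none",
        correlation="sigma1",
        coefficients="beta_eq",
    )
    base.update(overrides)
    return b.ScenarioSpec(**base)


def make_cohort(spec: b.ScenarioSpec, rep: int = 0, master_seed: int = MASTER_SEED):
    corr = b.build_correlation_matrix(spec.correlation, spec.k)
    coeffs = b.build_coefficients(spec.coefficients, spec.k)
    rate = b.calibrate_censoring_rate(spec, calibration_seed(spec, master_seed))
    cohort = b.simulate_cohort(spec, coeffs, corr, rate, run_seed(spec, rep, master_seed))
    return cohort, coeffs, rate


@pytest.fixture(scope="session")
def toy_cohort():
    return b.make_fixture("toy_cohort", seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One default K=12 low-censoring trial, shared across read-only tests."""
    spec = default_spec()
    cohort, coeffs, rate = make_cohort(spec)
    return cohort, spec, coeffs, rate
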
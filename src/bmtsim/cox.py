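"""Proportional-hazards fitting by Newton-Raphson partial-likelihood
maximization, plus the interaction-focused inference primitives.

The engine is a vectorized in-package maximizer tuned for the simulation's
workload: thousands of small-``p`` fits per cohort during forward selection.
Data are sorted once per cohort (:class:`CoxData`), after which any column
subset can be fitted cheaply, optionally warm-started from a previous fit.

Event times here are continuous, so tied event times occur with probability
zero; the partial likelihood is evaluated in its no-ties form (identical to
both Breslow's and Efron's formulas on tie-free data).  If tied times are
supplied the risk sets follow Breslow's approximation.

Inference on the treatment x biomarker term uses the two-sided Wald test and
the symmetric 95 % normal-quantile confidence interval
``estimate -/+ 1.959964 * sqrt(variance)``.  The information criterion is the
``2*loglik - 2*p`` form (larger is better; selection maximizes it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FitResult",
    "InteractionInference",
    "CoxData",
    "cohort_design",
    "fit_cox",
    "interaction_inference",
    "model_aic",
    "ConvergenceError",
    "INTERACTION_TERM",
    "PHI_975",
]

#: 97.5 % standard-normal quantile used for the 95 % Wald interval.
PHI_975 = 1.959964

#: Canonical column label of the treatment x biomarker product term.
INTERACTION_TERM = "treatment:biomarker"

# Newton-Raphson controls: relative partial-loglik change below _TOL stops,
# at most _MAX_ITER iterations, at most _MAX_HALVINGS step halvings per
# iteration.  Coefficients with |beta| > _BETA_BOUND are declared divergent.
_TOL = 1e-9
_MAX_ITER = 100
_MAX_HALVINGS = 25
_BETA_BOUND = 50.0


class ConvergenceError(RuntimeError):
    """Raised when inference is requested from a non-converged fit."""


@dataclass
class FitResult:
    """One fitted proportional-hazards model.

    ``covariance`` is the inverse observed information at the maximum.  When
    ``converged`` is False the numeric fields hold the last iterate and must
    not be used for inference.
    """

    covariate_names: tuple[str, ...]
    coefficients: np.ndarray
    covariance: np.ndarray
    partial_loglik: float
    converged: bool
    n_events: int
    n_parameters: int


@dataclass(frozen=True)
class InteractionInference:
    """Wald inference for the treatment x biomarker coefficient."""

    estimate: float
    variance: float
    p_value: float
    ci_low: float
    ci_high: float


class CoxData:
    """Survival data pre-sorted for repeated partial-likelihood fits.

    Rows are ordered by decreasing follow-up time so risk sets are prefixes;
    with tied times the prefix extends through the tie block (Breslow).
    """

    def __init__(
        self,
        time: np.ndarray,
        event: np.ndarray,
        design: np.ndarray,
        names: Sequence[str],
    ) -> None:
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        design = np.asarray(design, dtype=float)
        if design.ndim != 2 or design.shape[0] != time.shape[0]:
            raise ValueError("design must be (n, p) aligned with time")
        if design.shape[1] != len(names):
            raise ValueError("names must label every design column")
        order = np.argsort(-time, kind="stable")
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.design = np.ascontiguousarray(design[order])
        self.names = tuple(names)
        self.n_events = int(self.event.sum())
        if self.n_events == 0:
            raise ValueError("no events observed; partial likelihood undefined")
        # index of the last row sharing each row's time (risk-set boundary)
        neg_t = -self.time
        self._risk_end = np.searchsorted(neg_t, neg_t, side="right") - 1
        self._event_rows = np.flatnonzero(self.event)
        self._event_risk_end = self._risk_end[self._event_rows]

    @property
    def n(self) -> int:
        return self.time.shape[0]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.names.index(nm) for nm in names]
        return self.design[:, idx]

    def fit(
        self, names: Sequence[str], *, initial: np.ndarray | None = None
    ) -> FitResult:
        """Fit the model with the given design columns.

        ``initial`` warm-starts Newton-Raphson (used heavily by forward
        selection).  Failure to converge is reported via the ``converged``
        flag, never an exception; constant columns and empty column sets
        raise ``ValueError``.
        """
        names = tuple(names)
        if not names:
            raise ValueError("empty covariate set")
        X = self.columns(names)
        spans = X.max(axis=0) - X.min(axis=0)
        if np.any(spans == 0):
            bad = [nm for nm, s in zip(names, spans) if s == 0]
            raise ValueError(f"constant design column(s): {bad}")
        beta, cov, loglik, ok = _newton(
            X, self._event_rows, self._event_risk_end, initial
        )
        return FitResult(
            covariate_names=names,
            coefficients=beta,
            covariance=cov,
            partial_loglik=loglik,
            converged=ok,
            n_events=self.n_events,
            n_parameters=len(names),
        )

    def partial_loglik_at(self, names: Sequence[str], beta: np.ndarray) -> float:
        """Partial log-likelihood of the named columns at a fixed beta."""
        X = self.columns(tuple(names))
        beta = np.asarray(beta, dtype=float)
        return _loglik(X, beta, self._event_rows, self._event_risk_end)

    def null_loglik(self) -> float:
        """Partial log-likelihood of the empty (beta = 0) model."""
        return _loglik(
            np.zeros((self.n, 0)), np.zeros(0), self._event_rows, self._event_risk_end
        )


def _prefix_sums(w: np.ndarray, X: np.ndarray):
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * X, axis=0)
    return s0, s1


def _loglik(X, beta, event_rows, event_risk_end) -> float:
    eta = X @ beta if X.shape[1] else np.zeros(X.shape[0])
    shift = eta.max() if eta.size else 0.0
    w = np.exp(eta - shift)
    s0 = np.cumsum(w)
    return float(
        np.sum(eta[event_rows] - shift - np.log(s0[event_risk_end]))
    )


def _derivs(X, beta, event_rows, event_risk_end):
    """Partial loglik, gradient, observed information at beta.

    The information's risk-set second-moment term sum_e S2(e)/S0(e) is
    rewritten as X^T diag(w * r) X with r_j = sum over events whose risk set
    contains row j of 1/S0(e) (a reverse cumulative sum), turning the
    naive (n, p, p) prefix-sum into one GEMM.
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)
    s0, s1 = _prefix_sums(w, X)
    s0e = s0[event_risk_end]
    s1e = s1[event_risk_end]
    ll = float(np.sum(eta[event_rows] - shift - np.log(s0e)))
    xbar = s1e / s0e[:, None]
    grad = X[event_rows].sum(axis=0) - xbar.sum(axis=0)
    inv0 = np.zeros(n)
    np.add.at(inv0, event_risk_end, 1.0 / s0e)
    r = np.cumsum(inv0[::-1])[::-1]
    info = X.T @ ((w * r)[:, None] * X) - xbar.T @ xbar
    return ll, grad, info


def _newton(X, event_rows, event_risk_end, initial):
    n, p = X.shape
    beta = np.zeros(p) if initial is None else np.asarray(initial, dtype=float).copy()
    if beta.shape != (p,) or not np.all(np.isfinite(beta)):
        beta = np.zeros(p)

    ll = -np.inf
    info = np.eye(p)
    converged = False
    for _ in range(_MAX_ITER):
        ll, grad, info = _derivs(X, beta, event_rows, event_risk_end)
        if not np.isfinite(ll):
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # damped update: halve until the partial loglik does not decrease
        scale = 1.0
        for _ in range(_MAX_HALVINGS):
            candidate = beta + scale * step
            ll_new = _loglik(X, candidate, event_rows, event_risk_end)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = candidate
        if abs(ll_new - ll) < _TOL * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break

    if converged:
        # curvature at the solution, for the covariance
        ll, _, info = _derivs(X, beta, event_rows, event_risk_end)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            converged = False
    else:
        cov = np.full((p, p), np.nan)

    if converged and (
        not np.all(np.isfinite(beta))
        or not np.all(np.isfinite(cov))
        or np.any(np.diag(cov) <= 0)
        or np.any(np.abs(beta) > _BETA_BOUND)
    ):
        converged = False
    return beta, cov, ll, converged


def cohort_design(cohort) -> CoxData:
    """Pre-sorted design for a simulated trial.

    Columns: ``treatment``, ``biomarker``, ``treatment:biomarker``,
    ``x1`` .. ``xK``.
    """
    cols = [
        cohort.treatment,
        cohort.biomarker,
        cohort.treatment * cohort.biomarker,
    ]
    names = ["treatment", "biomarker", INTERACTION_TERM]
    design = np.column_stack(cols + [cohort.covariates])
    names += [f"x{j + 1}" for j in range(cohort.k)]
    return CoxData(cohort.time, cohort.event, design, names)


def fit_cox(cohort, covariate_set: Sequence[str]) -> FitResult:
    """Fit a proportional-hazards model on a cohort's named columns.

    Convenience wrapper over :class:`CoxData`; strategies that fit many
    models per cohort should build the :class:`CoxData` once instead.
    """
    return cohort_design(cohort).fit(covariate_set)


def interaction_inference(fit: FitResult) -> InteractionInference:
    """Wald test and 95 % CI for the treatment x biomarker coefficient.

    Raises :class:`ConvergenceError` for non-converged fits (the run is then
    excluded for that strategy) and ``ValueError`` when the fit does not
    contain the interaction term.
    """
    if not fit.converged:
        raise ConvergenceError("inference requested from a non-converged fit")
    try:
        j = fit.covariate_names.index(INTERACTION_TERM)
    except ValueError:
        raise ValueError(f"fit does not contain the {INTERACTION_TERM!r} term") from None
    estimate = float(fit.coefficients[j])
    variance = float(fit.covariance[j, j])
    se = np.sqrt(variance)
    z = estimate / se
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return InteractionInference(
        estimate=estimate,
        variance=variance,
        p_value=p_value,
        ci_low=estimate - PHI_975 * se,
        ci_high=estimate + PHI_975 * se,
    )


def model_aic(fit: FitResult) -> float:
    """Information criterion ``2*loglik - 2*p`` (larger is better).

    This is the mirror image of the conventional minimized AIC; model
    rankings are identical under either sign convention.
    """
    if not fit.converged:
        raise ConvergenceError("criterion requested from a non-converged fit")
    return 2.0 * fit.partial_loglik - 2.0 * fit.n_parameters
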
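"""The six covariate-inclusion strategies for interaction estimation.

Every strategy ends with a proportional-hazards fit that contains treatment,
biomarker and their product term; they differ only in which prognostic
covariates X_1..X_K join the model:

* ``main``          — none (interaction model only).
* ``true``          — exactly the covariates with nonzero true coefficients
                      (perfect prior knowledge; equals ``full`` when every
                      coefficient is nonzero).
* ``aic_a``         — greedy forward selection by the 2*loglik - 2*p
                      criterion, with {T, B, TxB} as the protected base.
* ``aic_b``         — the same forward selection but with only {T} as the
                      base and the biomarker excluded from candidacy; B and
                      TxB are added afterwards and the model refitted.
* ``significance``  — every covariate whose single-covariate model shows a
                      two-sided Wald p below the screening level (0.05).
* ``full``          — all K covariates, regardless of the data.

Non-convergence of a strategy's final fit marks that run as excluded for
that strategy only; it is recorded, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cohort import Cohort
from .cox import (
    INTERACTION_TERM,
    ConvergenceError,
    CoxData,
    FitResult,
    InteractionInference,
    cohort_design,
    interaction_inference,
    model_aic,
)

__all__ = [
    "STRATEGY_NAMES",
    "StrategyRecord",
    "forward_select",
    "strategy_main",
    "strategy_true",
    "strategy_full",
    "strategy_aic_a",
    "strategy_aic_b",
    "strategy_significance",
    "run_all_strategies",
]

#: Canonical strategy order (column order of the study's result tables).
STRATEGY_NAMES = ("main", "true", "aic_a", "aic_b", "significance", "full")

_BASE_TERMS = ("treatment", "biomarker", INTERACTION_TERM)
_DEFAULT_SCREENING_ALPHA = 0.05


@dataclass
class StrategyRecord:
    """Per-run outcome of one strategy.

    ``inference`` is None when the final fit did not converge;
    ``selected_prognostic`` always reflects the prognostic covariates the
    strategy attempted to include (excluding T, B, TxB).
    """

    strategy: str
    inference: InteractionInference | None
    selected_prognostic: tuple[str, ...]
    converged: bool

    @property
    def n_selected(self) -> int:
        return len(self.selected_prognostic)


def _as_coxdata(cohort: Cohort | CoxData) -> CoxData:
    return cohort if isinstance(cohort, CoxData) else cohort_design(cohort)


def _record(name: str, data: CoxData, prognostic: Sequence[str]) -> StrategyRecord:
    """Final refit on base terms + prognostic set, with recorded convergence."""
    prognostic = tuple(prognostic)
    try:
        fit = data.fit(_BASE_TERMS + prognostic)
    except ValueError:
        return StrategyRecord(name, None, prognostic, converged=False)
    if not fit.converged:
        return StrategyRecord(name, None, prognostic, converged=False)
    return StrategyRecord(name, interaction_inference(fit), prognostic, converged=True)


def forward_select(
    cohort: Cohort | CoxData,
    base_set: Sequence[str],
    candidates: Sequence[str],
) -> tuple[list[str], FitResult]:
    """Greedy forward selection maximizing ``2*loglik - 2*p``.

    At each step every remaining candidate is fitted on top of the current
    model; the best one joins if it strictly improves the criterion, ties
    resolved to the lowest-index candidate.  Candidates whose augmented fit
    fails to converge are skipped at that step.  Returns the selected labels
    (in selection order) and the final fit.  Raises
    :class:`~bmtsim.cox.ConvergenceError` when the base model itself does
    not converge.
    """
    data = _as_coxdata(cohort)
    base = list(base_set)
    candidates = list(candidates)
    if set(base) & set(candidates):
        raise ValueError("candidates must be disjoint from the base set")

    current = data.fit(base)
    if not current.converged:
        raise ConvergenceError("base model did not converge")
    current_aic = model_aic(current)
    selected: list[str] = []

    while candidates:
        best_aic = current_aic
        best_idx = -1
        best_fit = None
        for i, cand in enumerate(candidates):
            warm = np.append(current.coefficients, 0.0)
            try:
                fit = data.fit(base + selected + [cand], initial=warm)
            except ValueError:
                continue
            if not fit.converged:
                continue
            aic = model_aic(fit)
            if aic > best_aic:  # strict improvement; first max wins ties
                best_aic = aic
                best_idx = i
                best_fit = fit
        if best_idx < 0:
            break
        selected.append(candidates.pop(best_idx))
        current, current_aic = best_fit, best_aic
    return selected, current


def strategy_main(cohort: Cohort | CoxData) -> StrategyRecord:
    """Interaction model only, ignoring every prognostic covariate."""
    return _record("main", _as_coxdata(cohort), ())


def strategy_true(
    cohort: Cohort | CoxData, truth: Sequence[int] | np.ndarray
) -> StrategyRecord:
    """Oracle model: exactly the truly associated covariates.

    ``truth`` holds 0-based indices into X_1..X_K (as produced by
    :func:`bmtsim.cohort.build_coefficients`).
    """
    data = _as_coxdata(cohort)
    names = tuple(f"x{int(j) + 1}" for j in truth)
    return _record("true", data, names)


def strategy_full(cohort: Cohort | CoxData) -> StrategyRecord:
    """All K prognostic covariates, independent of the data."""
    data = _as_coxdata(cohort)
    names = tuple(nm for nm in data.names if nm.startswith("x"))
    return _record("full", data, names)


def strategy_aic_a(cohort: Cohort | CoxData) -> StrategyRecord:
    """Forward selection with the protected base {T, B, TxB}."""
    data = _as_coxdata(cohort)
    candidates = [nm for nm in data.names if nm.startswith("x")]
    try:
        selected, fit = forward_select(data, list(_BASE_TERMS), candidates)
    except ConvergenceError:
        return StrategyRecord("aic_a", None, (), converged=False)
    if not fit.converged:
        return StrategyRecord("aic_a", None, tuple(selected), converged=False)
    return StrategyRecord(
        "aic_a", interaction_inference(fit), tuple(selected), converged=True
    )


def strategy_aic_b(cohort: Cohort | CoxData) -> StrategyRecord:
    """Forward selection from base {T} with B excluded, then add B and TxB.

    Selection sees neither the biomarker nor the interaction; both are
    appended afterwards and the model refitted for inference.
    """
    data = _as_coxdata(cohort)
    candidates = [nm for nm in data.names if nm.startswith("x")]
    try:
        selected, _ = forward_select(data, ["treatment"], candidates)
    except ConvergenceError:
        return StrategyRecord("aic_b", None, (), converged=False)
    return _record("aic_b", data, selected)


def strategy_significance(
    cohort: Cohort | CoxData, screening_alpha: float = _DEFAULT_SCREENING_ALPHA
) -> StrategyRecord:
    """Keep covariates significant in single-covariate screening models.

    Each X_j is screened in a proportional-hazards model containing only
    X_j; it is kept when the two-sided Wald p-value is below
    ``screening_alpha``.  Screening fits that fail to converge count as not
    selected.
    """
    data = _as_coxdata(cohort)
    kept = []
    for nm in data.names:
        if not nm.startswith("x"):
            continue
        try:
            fit = data.fit([nm])
        except ValueError:
            continue
        if not fit.converged:
            continue
        se = float(np.sqrt(fit.covariance[0, 0]))
        z = float(fit.coefficients[0]) / se
        # two-sided Wald screen
        if 2.0 * norm.sf(abs(z)) < screening_alpha:
            kept.append(nm)
    return _record("significance", data, kept)


def run_all_strategies(
    cohort: Cohort,
    truth: Sequence[int] | np.ndarray,
    *,
    strategies: Sequence[str] = STRATEGY_NAMES,
    screening_alpha: float = _DEFAULT_SCREENING_ALPHA,
) -> list[StrategyRecord]:
    """Apply the requested strategies to one cohort, sharing the sorted design."""
    data = cohort_design(cohort)
    out: list[StrategyRecord] = []
    for name in strategies:
        if name == "main":
            out.append(strategy_main(data))
        elif name == "true":
            out.append(strategy_true(data, truth))
        elif name == "full":
            out.append(strategy_full(data))
        elif name == "aic_a":
            out.append(strategy_aic_a(data))
        elif name == "aic_b":
            out.append(strategy_aic_b(data))
        elif name == "significance":
            out.append(strategy_significance(data, screening_alpha))
        else:
            raise ValueError(f"unknown strategy {name!r}")
    return out
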
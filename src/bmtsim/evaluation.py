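"""Scenario-level Monte-Carlo metrics.

Per-run strategy records (long format, one row per run x strategy) are
aggregated into the study's operating characteristics: the rejection
proportion of the interaction Wald test (type-I error under the null, power
otherwise), confidence-interval coverage of the true interaction
coefficient, the mean number of prognostic covariates included, estimator
bias, and non-convergence bookkeeping.  Non-converged runs are excluded
from every numerator and denominator but always tallied.

A rejection proportion above 7 % is flagged as an inflated type-I error
(strictly greater than 0.07; only meaningful for null scenarios).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioSummary",
    "records_to_frame",
    "rejection_proportion",
    "coverage",
    "mean_selected",
    "flag_inflated_type1",
    "nonconvergence_tally",
    "summarize_estimates",
    "summarize_scenario",
    "summarize_records",
    "pivot_summary",
    "TYPE1_INFLATION_THRESHOLD",
]

TYPE1_INFLATION_THRESHOLD = 0.07
_DEFAULT_ALPHA = 0.05

RECORD_COLUMNS = (
    "scenario_id",
    "rep",
    "strategy",
    "estimate",
    "variance",
    "p_value",
    "ci_low",
    "ci_high",
    "n_selected",
    "selected",
    "converged",
)


@dataclass
class ScenarioSummary:
    """Aggregates for one scenario x strategy cell."""

    scenario_id: str
    strategy: str
    n_runs_total: int
    n_converged: int
    rejection_proportion: float
    coverage: float
    mean_selected: float
    bias_mean: float
    type1_inflated: bool


def records_to_frame(records, scenario_id: str, rep: int) -> pd.DataFrame:
    """Convert StrategyRecord objects for one run into long-format rows."""
    rows = []
    for rec in records:
        inf = rec.inference
        rows.append(
            {
                "scenario_id": scenario_id,
                "rep": rep,
                "strategy": rec.strategy,
                "estimate": inf.estimate if inf else np.nan,
                "variance": inf.variance if inf else np.nan,
                "p_value": inf.p_value if inf else np.nan,
                "ci_low": inf.ci_low if inf else np.nan,
                "ci_high": inf.ci_high if inf else np.nan,
                "n_selected": rec.n_selected,
                "selected": "|".join(rec.selected_prognostic),
                "converged": bool(rec.converged),
            }
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def _converged(records: pd.DataFrame) -> pd.DataFrame:
    return records[records["converged"].astype(bool)]


def rejection_proportion(records: pd.DataFrame, alpha: float = _DEFAULT_ALPHA) -> float:
    """Fraction of converged runs with Wald p < alpha (strict).

    Returns NaN (a missing cell) when no run converged.
    """
    conv = _converged(records)
    if len(conv) == 0:
        return float("nan")
    return float((conv["p_value"] < alpha).mean())


def coverage(records: pd.DataFrame, true_interaction: float) -> float:
    """Fraction of converged runs whose CI contains the true coefficient."""
    conv = _converged(records)
    if len(conv) == 0:
        return float("nan")
    covered = (conv["ci_low"] <= true_interaction) & (true_interaction <= conv["ci_high"])
    return float(covered.mean())


def mean_selected(records: pd.DataFrame) -> float:
    """Mean number of prognostic covariates included, over converged runs."""
    conv = _converged(records)
    if len(conv) == 0:
        return float("nan")
    return float(conv["n_selected"].mean())


def flag_inflated_type1(prop: float) -> bool:
    """True when the rejection proportion strictly exceeds 7 %."""
    return bool(prop > TYPE1_INFLATION_THRESHOLD)


def nonconvergence_tally(records: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy counts and fractions of non-converged runs."""
    grouped = records.groupby("strategy", sort=False)
    out = grouped["converged"].agg(
        n_runs_total="size", n_failed=lambda s: int((~s.astype(bool)).sum())
    )
    out["fraction_failed"] = out["n_failed"] / out["n_runs_total"]
    return out.reset_index()


def summarize_estimates(records: pd.DataFrame, true_interaction: float) -> dict:
    """Location summary of the interaction estimates among converged runs."""
    conv = _converged(records)
    est = conv["estimate"].to_numpy(dtype=float)
    if est.size == 0:
        return {
            "mean": float("nan"),
            "median": float("nan"),
            "q25": float("nan"),
            "q75": float("nan"),
            "bias_mean": float("nan"),
        }
    return {
        "mean": float(np.mean(est)),
        "median": float(np.median(est)),
        "q25": float(np.percentile(est, 25)),
        "q75": float(np.percentile(est, 75)),
        "bias_mean": float(np.mean(est) - true_interaction),
    }


def summarize_scenario(
    records: pd.DataFrame,
    scenario_id: str,
    strategy: str,
    true_interaction: float,
    alpha: float = _DEFAULT_ALPHA,
) -> ScenarioSummary:
    """Summary for one scenario x strategy slice of the record table."""
    sub = records[
        (records["scenario_id"] == scenario_id) & (records["strategy"] == strategy)
    ]
    prop = rejection_proportion(sub, alpha)
    return ScenarioSummary(
        scenario_id=scenario_id,
        strategy=strategy,
        n_runs_total=int(len(sub)),
        n_converged=int(sub["converged"].astype(bool).sum()),
        rejection_proportion=prop,
        coverage=coverage(sub, true_interaction),
        mean_selected=mean_selected(sub),
        bias_mean=summarize_estimates(sub, true_interaction)["bias_mean"],
        type1_inflated=flag_inflated_type1(prop),
    )


def summarize_records(
    records: pd.DataFrame, truth_by_scenario: dict[str, float], alpha: float = _DEFAULT_ALPHA
) -> pd.DataFrame:
    """One summary row per scenario x strategy present in the record table.

    ``truth_by_scenario`` maps scenario_id to the true interaction
    coefficient used for coverage and bias.
    """
    rows = []
    for (sid, strat), _ in records.groupby(["scenario_id", "strategy"], sort=False):
        summ = summarize_scenario(records, sid, strat, truth_by_scenario[sid], alpha)
        rows.append(vars(summ))
    return pd.DataFrame(rows)


def pivot_summary(summary: pd.DataFrame, value: str = "rejection_proportion") -> pd.DataFrame:
    """Wide layout with strategies as columns (the result-table shape)."""
    return summary.pivot(index="scenario_id", columns="strategy", values=value)
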
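"""Factorial grid of simulation settings and deterministic per-run seeding.

A scenario is one cell of the fully crossed design over

* ``k`` — number of candidate prognostic covariates (12, 24 or 36),
* ``censoring_band`` — target censored fraction, ``low`` = 30-40 % or
  ``high`` = 60-70 %,
* ``interaction`` — strength of the biomarker-treatment interaction
  (``none``, ``quantitative`` = ln 1.1, ``qualitative`` = ln 1.33),
* ``correlation`` — covariance structure of (biomarker, covariates)
  (``sigma1`` independent, ``sigma2`` exchangeable 0.5, ``sigma3`` block),
* ``coefficients`` — prognostic effect pattern (``beta_eq`` all ln 1.1,
  ``beta_v`` cycling ln 1.2 / ln 1.1 / 0),

giving 3 x 2 x 3 x 3 x 2 = 108 scenarios at the defaults.  The treatment
log hazard ratio is fixed at ln 0.75 and the biomarker main effect at
ln 1.25 in every scenario; trials have 500 subjects, an administrative
horizon of 5 years and unit baseline hazard.

The canonical enumeration order is lexicographic over
(k, censoring_band, interaction, correlation, coefficients) with the factor
levels in the order listed above; it is frozen and stable across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioSpec",
    "FACTOR_LEVELS",
    "INTERACTION_BETA",
    "CENSORING_BANDS",
    "enumerate_scenarios",
    "run_seed",
    "calibration_seed",
    "scenarios_to_frame",
]

#: Factor levels in canonical order.  Enumeration and seeding both key on
#: these orders; do not reorder.
FACTOR_LEVELS: Mapping[str, tuple] = {
    "k": (12, 24, 36),
    "censoring_band": ("low", "high"),
    "interaction": ("none", "quantitative", "qualitative"),
    "correlation": ("sigma1", "sigma2", "sigma3"),
    "coefficients": ("beta_eq", "beta_v"),
}

#: True interaction log hazard ratio by interaction level.
INTERACTION_BETA: Mapping[str, float] = {
    "none": 0.0,
    "quantitative": math.log(1.1),
    "qualitative": math.log(1.33),
}

#: Target censored-fraction interval by band.
CENSORING_BANDS: Mapping[str, tuple[float, float]] = {
    "low": (0.30, 0.40),
    "high": (0.60, 0.70),
}


class ConfigurationError(ValueError):
    """Raised for unknown factor names or levels in grid overrides."""


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation design.

    Parameters not part of the factorial (sample size, fixed main effects,
    horizon, baseline hazard) carry the study-wide defaults but may be
    overridden, e.g. for scaled-down runs or calibration experiments.
    """

    k: int
    censoring_band: str
    interaction: str
    correlation: str
    coefficients: str
    n_subjects: int = 500
    n_reps: int = 1000
    beta_t: float = math.log(0.75)
    beta_b: float = math.log(1.25)
    admin_horizon: float = 5.0
    baseline_hazard: float = 1.0

    def __post_init__(self) -> None:
        for name in FACTOR_LEVELS:
            value = getattr(self, name)
            if value not in FACTOR_LEVELS[name]:
                raise ConfigurationError(
                    f"unknown level {value!r} for factor {name!r}; "
                    f"expected one of {FACTOR_LEVELS[name]}"
                )
        if self.n_subjects < 1 or self.n_reps < 1:
            raise ConfigurationError("n_subjects and n_reps must be positive")

    @property
    def beta_interaction(self) -> float:
        """True interaction coefficient beta_TxB for this scenario."""
        return INTERACTION_BETA[self.interaction]

    @property
    def censoring_interval(self) -> tuple[float, float]:
        """Target (low, high) censored fraction for this scenario's band."""
        return CENSORING_BANDS[self.censoring_band]

    @property
    def scenario_id(self) -> str:
        """Stable human-readable identifier, e.g. ``k12-low-none-sigma1-beta_eq``."""
        return (
            f"k{self.k}-{self.censoring_band}-{self.interaction}"
            f"-{self.correlation}-{self.coefficients}"
        )

    def factor_key(self) -> tuple[int, ...]:
        """Indices of this scenario's factor levels in canonical order."""
        return tuple(
            FACTOR_LEVELS[name].index(getattr(self, name)) for name in FACTOR_LEVELS
        )


def enumerate_scenarios(
    overrides: Mapping[str, Sequence] | None = None,
    *,
    n_subjects: int = 500,
    n_reps: int = 1000,
) -> list[ScenarioSpec]:
    """Enumerate the factorial grid in canonical order.

    ``overrides`` may restrict any factor to a subset of its default levels,
    e.g. ``{"k": [12], "censoring_band": ["low"]}``.  With no overrides the
    full 108-scenario grid is returned, sorted lexicographically by
    (k, censoring_band, interaction, correlation, coefficients) with levels
    in their canonical order.

    Raises :class:`ConfigurationError` for unknown factors or levels.
    """
    overrides = dict(overrides or {})
    levels: dict[str, tuple] = {}
    for name, defaults in FACTOR_LEVELS.items():
        chosen = overrides.pop(name, defaults)
        if isinstance(chosen, (str, int)):
            chosen = (chosen,)
        chosen = tuple(chosen)
        for lvl in chosen:
            if lvl not in defaults:
                raise ConfigurationError(
                    f"unknown level {lvl!r} for factor {name!r}; "
                    f"expected a subset of {defaults}"
                )
        # preserve canonical level order regardless of override order
        levels[name] = tuple(lvl for lvl in defaults if lvl in chosen)
    if overrides:
        raise ConfigurationError(f"unknown factor(s) in overrides: {sorted(overrides)}")

    specs = []
    for k in levels["k"]:
        for cens in levels["censoring_band"]:
            for inter in levels["interaction"]:
                for corr in levels["correlation"]:
                    for coef in levels["coefficients"]:
                        specs.append(
                            ScenarioSpec(
                                k=k,
                                censoring_band=cens,
                                interaction=inter,
                                correlation=corr,
                                coefficients=coef,
                                n_subjects=n_subjects,
                                n_reps=n_reps,
                            )
                        )
    return specs


def _seed_sequence(spec: ScenarioSpec, master_seed: int, stream: int) -> np.random.SeedSequence:
    # Counter-based child-seed derivation: the spawn key encodes the factor
    # levels (not the enumeration position) plus a stream index, so seeds are
    # independent of execution order and of which grid subset is run.
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(*spec.factor_key(), int(stream))
    )


#: Stream index reserved for censoring-rate calibration (outside the
#: rep-index range, which is capped far below this value).
_CALIBRATION_STREAM = 2**30


def run_seed(spec: ScenarioSpec, rep_index: int, master_seed: int) -> int:
    """Deterministic 128-bit seed for one simulation run.

    Injective over (scenario factor levels, rep_index) for a fixed master
    seed; suitable for :func:`numpy.random.default_rng`.  Raises
    ``ValueError`` when ``rep_index`` is outside ``[0, spec.n_reps)``.
    """
    rep_index = int(rep_index)
    if not 0 <= rep_index < spec.n_reps:
        raise ValueError(
            f"rep_index {rep_index} out of range [0, {spec.n_reps}) for {spec.scenario_id}"
        )
    if rep_index >= _CALIBRATION_STREAM:
        raise ValueError("rep_index exceeds the reserved stream range")
    state = _seed_sequence(spec, master_seed, rep_index).generate_state(2, np.uint64)
    return (int(state[0]) << 64) | int(state[1])


def calibration_seed(spec: ScenarioSpec, master_seed: int) -> int:
    """Seed for the scenario's censoring-rate calibration draw.

    Uses a stream index disjoint from every rep index, so calibration never
    shares randomness with the simulation runs.
    """
    state = _seed_sequence(spec, master_seed, _CALIBRATION_STREAM).generate_state(2, np.uint64)
    return (int(state[0]) << 64) | int(state[1])


def scenarios_to_frame(specs: Iterable[ScenarioSpec]) -> pd.DataFrame:
    """Tabulate scenarios, one row each, with a stable ``scenario_id`` column."""
    rows = []
    for spec in specs:
        rows.append(
            {
                "scenario_id": spec.scenario_id,
                "k": spec.k,
                "censoring_band": spec.censoring_band,
                "interaction": spec.interaction,
                "correlation": spec.correlation,
                "coefficients": spec.coefficients,
                "beta_interaction": spec.beta_interaction,
                "n_subjects": spec.n_subjects,
                "n_reps": spec.n_reps,
            }
        )
    return pd.DataFrame(rows)
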
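"""The Markov cohort engine: transition matrices, mortality and the trace.

Each annual cycle resolves death first (age-banded all-cause mortality, with
the cause-specific T2D death rate reallocated as excess risk to T2D
occupants) and then distributes the surviving mass across the allowed
glucose-state transitions, evaluated from the logistic risk equations at the
cohort's expected covariates.  Direct moves between pre-diabetic states and
NGT→T2D within one year are structurally impossible.  Costs and QALYs
accrue to cycle-start occupants and are discounted from the starting year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .economics import CEAResult
from .risk import (
    CATEGORICAL_FACTORS,
    InterventionEffect,
    apply_intervention,
    decay_weight,
    decayed_profile,
    expected_covariates,
    transition_probability,
)
from .states import GlucoseState, LIVING_STATES, N_STATES, PREDIABETIC_STATES

__all__ = [
    "MortalityTable",
    "ScenarioConfig",
    "CohortTrace",
    "mortality_probability",
    "build_transition_matrix",
    "run_cohort",
    "run_cea",
]

_ATOL = 1e-9


@dataclass(frozen=True)
class MortalityTable:
    """Annual death probabilities in contiguous age bands.

    Columns: band ``[age_low, age_high)``, all-cause probability, and the
    T2D-cause-specific component of it (population rate, not the excess
    risk of a person with T2D).
    """

    bands: tuple[tuple[float, float, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = None
        for lo, hi, q_all, q_t2d in self.bands:
            if hi <= lo:
                raise ValueError(f"empty band [{lo}, {hi})")
            if prev_high is not None and abs(lo - prev_high) > _ATOL:
                raise ValueError(f"bands not contiguous at age {lo}")
            if not (0.0 <= q_all <= 1.0 and 0.0 <= q_t2d <= 1.0):
                raise ValueError(f"probability out of [0, 1] in band [{lo}, {hi})")
            if q_t2d > q_all + _ATOL:
                raise ValueError(
                    f"T2D-specific exceeds all-cause mortality in band [{lo}, {hi})"
                )
            prev_high = hi

    @property
    def max_age(self) -> float:
        return self.bands[-1][1]

    def lookup(self, age: float) -> tuple[float, float]:
        """(all-cause, T2D-specific) annual probability for an attained age."""
        for lo, hi, q_all, q_t2d in self.bands:
            if lo <= age < hi:
                return q_all, q_t2d
        if abs(age - self.max_age) <= _ATOL:  # closed upper end
            return self.bands[-1][2], self.bands[-1][3]
        raise ValueError(f"age {age} outside mortality table [0, {self.max_age}]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.bands), columns=["age_low", "age_high", "all_cause", "t2d_specific"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MortalityTable":
        cols = ["age_low", "age_high", "all_cause", "t2d_specific"]
        return cls(bands=tuple(tuple(float(x) for x in row) for row in df[cols].to_numpy()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def mortality_probability(
    mortality: MortalityTable,
    age: float,
    state: GlucoseState,
    t2d_prevalence: float = 0.061,
) -> float:
    """Annual death probability for one state at one age.

    Living non-T2D states get the cause-deleted rate (all-cause minus the
    T2D-specific component); T2D occupants additionally carry the
    population T2D death rate divided by the T2D prevalence share, so that
    cause-specific deaths load entirely on the prevalent cases.
    """
    if state is GlucoseState.DEAD:
        return 1.0
    q_all, q_t2d = mortality.lookup(age)
    q = q_all - q_t2d
    if state is GlucoseState.T2D and q_t2d > 0:
        if t2d_prevalence <= 0:
            raise ValueError("t2d_prevalence must be positive when T2D deaths occur")
        q += q_t2d / t2d_prevalence
    return min(q, 1.0)


#: Allowed glucose transitions (everything else except self-loops is structurally zero).
_ALLOWED = {
    (GlucoseState.NGT, GlucoseState.IFG),
    (GlucoseState.NGT, GlucoseState.IGT),
    (GlucoseState.NGT, GlucoseState.IFG_IGT),
    (GlucoseState.IFG, GlucoseState.NGT),
    (GlucoseState.IGT, GlucoseState.NGT),
    (GlucoseState.IFG_IGT, GlucoseState.NGT),
    (GlucoseState.IFG, GlucoseState.T2D),
    (GlucoseState.IGT, GlucoseState.T2D),
    (GlucoseState.IFG_IGT, GlucoseState.T2D),
    (GlucoseState.T2D, GlucoseState.IFG),
    (GlucoseState.T2D, GlucoseState.IGT),
    (GlucoseState.T2D, GlucoseState.IFG_IGT),
}


def build_transition_matrix(
    covariates: dict[str, float],
    equations,
    mortality: MortalityTable,
    age: float,
    *,
    disable_t2d_reversion: bool = False,
    t2d_prevalence: float = 0.061,
) -> np.ndarray:
    """6×6 annual transition matrix at one attained age.

    Death is resolved first; glucose transitions are conditional on
    survival, with residual mass staying in the current state.
    """
    M = np.zeros((N_STATES, N_STATES))
    M[GlucoseState.DEAD, GlucoseState.DEAD] = 1.0

    exits: dict[GlucoseState, list[tuple[GlucoseState, float]]] = {
        s: [] for s in LIVING_STATES
    }
    for eq in equations:
        if (eq.source, eq.target) not in _ALLOWED:
            raise ValueError(
                f"equation {eq.source.name}->{eq.target.name} violates model structure"
            )
        if disable_t2d_reversion and eq.source is GlucoseState.T2D:
            continue
        exits[eq.source].append((eq.target, transition_probability(eq, covariates)))

    for s in LIVING_STATES:
        q_death = mortality_probability(mortality, age, s, t2d_prevalence)
        total_exit = sum(p for _, p in exits[s])
        if total_exit > 1.0 + _ATOL:
            raise ValueError(
                f"transition probabilities out of state {s.name} sum to "
                f"{total_exit:.4f} > 1 at age {age}"
            )
        survive = 1.0 - q_death
        for target, p in exits[s]:
            M[s, target] = survive * p
        M[s, s] = survive * (1.0 - total_exit)
        M[s, GlucoseState.DEAD] = q_death
    return M


@dataclass(frozen=True)
class ScenarioConfig:
    """One arm of one sex×age scenario, plus sensitivity switches."""

    sex: str
    start_age: float
    arm: str = "control"
    discount_rate: float = 0.03
    horizon_age: float = 105.0
    starting_distribution: dict[GlucoseState, float] | None = None
    disable_t2d_reversion: bool = False
    state_cost_multiplier: float = 1.0
    intervention_cost_multiplier: float = 1.0
    #: rescale competing exits summing above 1 instead of erroring (PSA replicates)
    renormalize_exits: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("control", "intervention"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.horizon_age < self.start_age:
            raise ValueError("horizon must not precede the starting age")
        if self.starting_distribution is not None:
            total = sum(self.starting_distribution.values())
            if abs(total - 1.0) > _ATOL:
                raise ValueError(f"starting distribution sums to {total}, not 1")


@dataclass
class CohortTrace:
    """Per-cycle record of one arm: occupancy, ages, cost and QALY accruals."""

    ages: np.ndarray
    occupancy: np.ndarray  # (n_cycles, 6)
    cost: np.ndarray
    cost_discounted: np.ndarray
    qaly: np.ndarray
    qaly_discounted: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost_discounted.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_discounted.sum())

    @property
    def total_cost_undiscounted(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in GlucoseState])
        df.insert(0, "age", self.ages)
        df["cost"] = self.cost
        df["cost_discounted"] = self.cost_discounted
        df["qaly"] = self.qaly
        df["qaly_discounted"] = self.qaly_discounted
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class _CompiledEquations:
    """Risk equations flattened to a coefficient matrix for the cycle loop.

    Expected covariates are linear in the category probability vectors, so
    the intervention decay can blend covariate values directly instead of
    rebuilding profile objects each cycle; transition probabilities are then
    an inverse-logit of ``C @ cov + b``.  Numerically equivalent to
    :func:`build_transition_matrix` over the same equations.
    """

    _ORDER = ("sex", "age") + CATEGORICAL_FACTORS

    def __init__(self, equations, disable_t2d_reversion: bool = False) -> None:
        active = []
        for eq in equations:
            if (eq.source, eq.target) not in _ALLOWED:
                raise ValueError(
                    f"equation {eq.source.name}->{eq.target.name} violates model structure"
                )
            if disable_t2d_reversion and eq.source is GlucoseState.T2D:
                continue
            active.append(eq)
        idx = {name: i for i, name in enumerate(self._ORDER)}
        self.intercepts = np.array([eq.intercept for eq in active])
        self.coefs = np.zeros((len(active), len(self._ORDER)))
        for k, eq in enumerate(active):
            for name, c in eq.coefficients.items():
                self.coefs[k, idx[name]] = c
        self.sources = np.array([int(eq.source) for eq in active])
        self.targets = np.array([int(eq.target) for eq in active])
        self.age_index = idx["age"]

    def covariate_vector(self, covariates: dict[str, float]) -> np.ndarray:
        return np.array([covariates[name] for name in self._ORDER])

    def probabilities(self, cov_vec: np.ndarray) -> np.ndarray:
        lp = self.coefs @ cov_vec + self.intercepts
        out = np.empty_like(lp)
        pos = lp >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-lp[pos]))
        e = np.exp(lp[~pos])
        out[~pos] = e / (1.0 + e)
        return out

    def matrix(
        self,
        cov_vec: np.ndarray,
        death_probs: np.ndarray,
        renormalize_exits: bool = False,
    ) -> np.ndarray:
        """Assemble the 6×6 matrix: death first, transitions conditional on survival.

        Competing exit probabilities summing above 1 are an error by
        default; with ``renormalize_exits`` they are rescaled to sum to 1
        (used by the PSA, where independent beta draws of competing
        transitions can jointly overflow).
        """
        p = self.probabilities(cov_vec)
        M = np.zeros((N_STATES, N_STATES))
        M[GlucoseState.DEAD, GlucoseState.DEAD] = 1.0
        exit_sums = np.zeros(N_STATES)
        np.add.at(exit_sums, self.sources, p)
        for s in LIVING_STATES:
            if exit_sums[s] > 1.0 + _ATOL:
                if renormalize_exits:
                    p = np.where(self.sources == s, p / exit_sums[s], p)
                    exit_sums[s] = 1.0
                else:
                    raise ValueError(
                        f"transition probabilities out of state {s.name} sum to "
                        f"{exit_sums[s]:.4f} > 1"
                    )
        survive = 1.0 - death_probs
        M[self.sources, self.targets] = survive[self.sources] * p
        for s in LIVING_STATES:
            M[s, s] = survive[s] * (1.0 - exit_sums[s])
            M[s, GlucoseState.DEAD] = death_probs[s]
        return M


def run_cohort(config: ScenarioConfig, params) -> CohortTrace:
    """Advance one arm of a cohort from the starting age to the horizon.

    The cohort starts spread over the pre-diabetic states.  Each cycle, the
    intervention arm's risk-factor profile is the baseline blended toward
    the fully intervened profile with the linear decay weight; the matrix is
    rebuilt at the attained age; accruals (state costs, programme costs for
    the living, HUW-weighted QALYs) are recorded before the transition.
    """
    start = config.starting_distribution or params.starting_distribution
    occ = np.zeros(N_STATES)
    for state, share in start.items():
        occ[state] = share
    if abs(occ.sum() - 1.0) > _ATOL:
        raise ValueError("starting distribution does not sum to 1")

    baseline = params.baseline_profile(config.sex, config.start_age)
    is_intervention = config.arm == "intervention"

    compiled = _CompiledEquations(params.equations, config.disable_t2d_reversion)
    cov_base = compiled.covariate_vector(
        expected_covariates(baseline, params.coding)
    )
    if is_intervention:
        intervened = apply_intervention(baseline, params.effect)
        cov_delta = (
            compiled.covariate_vector(expected_covariates(intervened, params.coding))
            - cov_base
        )

    state_costs = params.costs.state_costs(config.state_cost_multiplier)
    cost_vec = np.array([state_costs[s] for s in GlucoseState])
    living = np.array([s is not GlucoseState.DEAD for s in GlucoseState], dtype=float)

    n_cycles = int(round(config.horizon_age - config.start_age)) + 1
    ages = config.start_age + np.arange(n_cycles, dtype=float)
    occupancy = np.empty((n_cycles, N_STATES))
    cost = np.empty(n_cycles)
    qaly = np.empty(n_cycles)
    disc = (1.0 + config.discount_rate) ** -np.arange(n_cycles, dtype=float)
    huw = None  # HUWs are constant once age passes the top anchor and the effect is gone

    for t in range(n_cycles):
        age = ages[t]
        w = decay_weight(t + 1, params.effect.effect_duration) if is_intervention else 0.0

        occupancy[t] = occ
        if huw is None or age <= 70.0 or w > 0.0:
            huw = np.array(
                [
                    params.utilities.utility_at(config.sex, age, config.arm, s, w)
                    for s in GlucoseState
                ]
            )
        c = float(occ @ cost_vec)
        if is_intervention:
            c += params.costs.intervention_cost(
                t, config.intervention_cost_multiplier
            ) * float(occ @ living)
        cost[t] = c
        qaly[t] = float(occ @ huw)

        if t < n_cycles - 1:
            cov_vec = cov_base + w * cov_delta if (is_intervention and w > 0) else cov_base.copy()
            cov_vec[compiled.age_index] = age
            deaths = np.array(
                [
                    mortality_probability(
                        params.mortality, age, s, params.t2d_prevalence
                    )
                    for s in LIVING_STATES
                ]
                + [1.0]
            )
            occ = occ @ compiled.matrix(cov_vec, deaths, config.renormalize_exits)

    return CohortTrace(
        ages=ages,
        occupancy=occupancy,
        cost=cost,
        cost_discounted=cost * disc,
        qaly=qaly,
        qaly_discounted=qaly * disc,
    )


def run_cea(config: ScenarioConfig, params) -> CEAResult:
    """Run both arms of a scenario and return the incremental comparison."""
    from dataclasses import replace

    control = run_cohort(replace(config, arm="control"), params)
    intervention = run_cohort(replace(config, arm="intervention"), params)
    return CEAResult(
        cost_control=control.total_cost,
        qaly_control=control.total_qaly,
        cost_intervention=intervention.total_cost,
        qaly_intervention=intervention.total_qaly,
    )
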
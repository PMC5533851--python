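"""Loading and bundling of model parameters.

All numeric inputs live in structured YAML files shipped under
``diabcea/data`` (risk equations, covariate coding, population marginals,
utilities, costs, mortality-generator calibration) so that alternative
values are a file edit, not a code change.  :class:`ModelParameters` bundles
everything one scenario run needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .economics import CostSchedule, UtilityTable
from .risk import (
    CovariateCoding,
    InterventionEffect,
    LogisticRiskEquation,
    RiskFactorProfile,
)
from .states import GlucoseState

__all__ = [
    "load_yaml_resource",
    "load_equations",
    "load_coding",
    "load_population",
    "load_utilities",
    "load_costs",
    "ModelParameters",
]


def load_yaml_resource(name: str) -> Any:
    """Parse a YAML file from the packaged data directory (or a filesystem path)."""
    p = Path(name)
    if p.exists():
        return yaml.safe_load(p.read_text())
    return yaml.safe_load(
        resources.files("diabcea.data").joinpath(name).read_text()
    )


def load_equations(source: str = "risk_equations.yaml") -> list[LogisticRiskEquation]:
    raw = load_yaml_resource(source)
    eqs = [
        LogisticRiskEquation(
            source=GlucoseState[e["from"]],
            target=GlucoseState[e["to"]],
            intercept=float(e["intercept"]),
            coefficients={k: float(v) for k, v in e["coefficients"].items()},
        )
        for e in raw["equations"]
    ]
    if len({(e.source, e.target) for e in eqs}) != len(eqs):
        raise ValueError("duplicate (source, target) pair in equation file")
    return eqs


def load_coding(source: str = "coding.yaml") -> CovariateCoding:
    raw = load_yaml_resource(source)
    sex = {str(k): float(v) for k, v in raw.pop("sex").items()}
    factors = {
        f: {str(c): float(v) for c, v in codes.items()} for f, codes in raw.items()
    }
    return CovariateCoding(sex=sex, factors=factors)


def _normalize(vec: dict[str, float]) -> dict[str, float]:
    total = sum(vec.values())
    return {k: float(v) / total for k, v in vec.items()}


def load_population(source: str = "population.yaml") -> dict[str, Any]:
    """Baseline marginals, intervention targets and starting distribution.

    Category vectors are renormalized on load (the published baseline
    physical-activity column over-counts slightly).
    """
    raw = load_yaml_resource(source)
    return {
        "baseline": {f: _normalize(v) for f, v in raw["baseline"].items()},
        "intervention_targets": {
            f: _normalize(v) for f, v in raw["intervention_targets"].items()
        },
        "starting_distribution": {
            GlucoseState[k]: float(v) for k, v in raw["starting_distribution"].items()
        },
    }


def load_utilities(source: str = "utilities.yaml") -> UtilityTable:
    raw = load_yaml_resource(source)["huw"]
    values: dict[tuple[str, int, str, GlucoseState], float] = {}
    for sex, by_age in raw.items():
        for age, by_arm in by_age.items():
            for arm, by_state in by_arm.items():
                for state, huw in by_state.items():
                    values[(sex, int(age), arm, GlucoseState[state])] = float(huw)
    return UtilityTable(values=values)


def load_costs(source: str = "costs.yaml") -> CostSchedule:
    raw = load_yaml_resource(source)
    return CostSchedule(
        t2d_direct=float(raw["t2d_direct"]),
        indirect_share=float(raw["indirect_share"]),
        prediabetes_share=float(raw["prediabetes_share"]),
        intervention_first_year=float(raw["intervention_first_year"]),
        intervention_followup=float(raw["intervention_followup"]),
        intervention_years=int(raw["intervention_years"]),
    )


@dataclass(frozen=True)
class ModelParameters:
    """Everything one cohort run needs, bundled.

    ``mortality`` is a :class:`diabcea.cohort.MortalityTable`;
    ``t2d_prevalence`` converts the population T2D death rate into an excess
    rate for T2D occupants (cause-specific deaths / prevalent cases).
    """

    equations: list[LogisticRiskEquation]
    coding: CovariateCoding
    baseline_factors: dict[str, dict[str, float]]
    starting_distribution: dict[GlucoseState, float]
    utilities: UtilityTable
    costs: CostSchedule
    mortality: Any
    effect: InterventionEffect
    t2d_prevalence: float = 0.061

    @classmethod
    def default(cls, mortality=None) -> "ModelParameters":
        """Parameter set reproducing the base case with packaged data files.

        If ``mortality`` is omitted, the default synthetic Swedish-like
        table is generated.
        """
        if mortality is None:
            from .synthetic import MortalityGeneratorParams, generate_mortality_table

            mortality = generate_mortality_table(MortalityGeneratorParams.default())
        pop = load_population()
        effect = InterventionEffect(
            weight_reduction_fraction=0.05,
            pa_target=pop["intervention_targets"]["physical_activity"],
            nutrition_target=pop["intervention_targets"]["nutrition"],
            effect_duration=7.0,
        )
        return cls(
            equations=load_equations(),
            coding=load_coding(),
            baseline_factors=pop["baseline"],
            starting_distribution=pop["starting_distribution"],
            utilities=load_utilities(),
            costs=load_costs(),
            mortality=mortality,
            effect=effect,
        )

    def baseline_profile(self, sex: str, age: float) -> RiskFactorProfile:
        return RiskFactorProfile(sex=sex, age=age, factors=dict(self.baseline_factors))

    def with_costs(self, costs: CostSchedule) -> "ModelParameters":
        return replace(self, costs=costs)

    def with_effect(self, effect: InterventionEffect) -> "ModelParameters":
        return replace(self, effect=effect)
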
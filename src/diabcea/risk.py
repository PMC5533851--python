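"""Risk factors, covariate coding and the logistic transition equations.

The cohort is represented at population level: each categorical risk factor
carries a probability vector over its categories, and the model evaluates
the logistic risk equations at the probability-weighted mean of the numeric
category codes ("mean values for risk factors").  The lifestyle intervention
acts on this representation by shifting the BMI distribution (a fractional
weight reduction moves mass obese→overweight→normal) and replacing the
physical-activity and nutrition vectors with target distributions; the
effect then fades linearly to zero over a fixed number of years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .states import GlucoseState

__all__ = [
    "CATEGORICAL_FACTORS",
    "RiskFactorProfile",
    "CovariateCoding",
    "LogisticRiskEquation",
    "InterventionEffect",
    "expected_covariates",
    "transition_probability",
    "apply_intervention",
    "decay_weight",
    "decayed_profile",
]

#: Categorical factors housed in a profile (sex and age are scalars).
CATEGORICAL_FACTORS = (
    "education",
    "triglyceride",
    "blood_pressure",
    "bmi",
    "smoking",
    "physical_activity",
    "snus",
    "nutrition",
    "marital_status",
    "family_history",
    "self_perceived_health",
)

_ATOL = 1e-9


def _normalized(vec: dict[str, float]) -> dict[str, float]:
    total = sum(vec.values())
    if total <= 0:
        raise ValueError("category vector has non-positive mass")
    return {k: v / total for k, v in vec.items()}


@dataclass(frozen=True)
class RiskFactorProfile:
    """Population-level risk-factor distribution plus scalar sex and age.

    ``factors`` maps each categorical factor name to a probability vector
    over its categories.  Vectors must be non-negative and sum to one.
    """

    sex: str
    age: float
    factors: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")
        for name in CATEGORICAL_FACTORS:
            if name not in self.factors:
                raise ValueError(f"missing factor {name!r}")
            vec = self.factors[name]
            if any(p < -_ATOL for p in vec.values()):
                raise ValueError(f"negative probability in factor {name!r}")
            if abs(sum(vec.values()) - 1.0) > _ATOL:
                raise ValueError(
                    f"factor {name!r} probabilities sum to {sum(vec.values())}, not 1"
                )

    def with_age(self, age: float) -> "RiskFactorProfile":
        return replace(self, age=age)

    def replace_factor(self, name: str, vec: dict[str, float]) -> "RiskFactorProfile":
        factors = dict(self.factors)
        factors[name] = _normalized(vec)
        return replace(self, factors=factors)


@dataclass(frozen=True)
class CovariateCoding:
    """Numeric code for each category of each factor, plus the sex coding."""

    sex: dict[str, float]
    factors: dict[str, dict[str, float]]

    def code(self, factor: str, category: str) -> float:
        try:
            return self.factors[factor][category]
        except KeyError:
            raise KeyError(
                f"no code for category {category!r} of factor {factor!r}"
            ) from None


@dataclass(frozen=True)
class LogisticRiskEquation:
    """One annual state-to-state transition: logit P = intercept + Σ coef·x."""

    source: GlucoseState
    target: GlucoseState
    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        if self.source is self.target:
            raise ValueError("source and target states must differ")

    def linear_predictor(self, covariates: dict[str, float]) -> float:
        lp = self.intercept
        for name, coef in self.coefficients.items():
            if name not in covariates:
                raise KeyError(
                    f"covariate {name!r} required by the "
                    f"{self.source.name}->{self.target.name} equation is missing"
                )
            lp += coef * covariates[name]
        return lp


@dataclass(frozen=True)
class InterventionEffect:
    """Lifestyle-change effect at the starting year and its duration.

    ``weight_reduction_fraction`` of the obese share moves to overweight and
    of the overweight share to normal weight.  ``pa_target`` and
    ``nutrition_target`` (category vectors) replace the baseline
    physical-activity and nutrition distributions; ``None`` leaves a factor
    untouched.  The whole effect decays linearly to zero over
    ``effect_duration`` years.
    """

    weight_reduction_fraction: float = 0.05
    pa_target: dict[str, float] | None = None
    nutrition_target: dict[str, float] | None = None
    effect_duration: float = 7.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_reduction_fraction <= 1.0:
            raise ValueError("weight_reduction_fraction must be in [0, 1]")
        if self.effect_duration <= 0:
            raise ValueError("effect_duration must be positive")


def expected_covariates(
    profile: RiskFactorProfile, coding: CovariateCoding
) -> dict[str, float]:
    """Probability-weighted mean code per factor; sex and age pass through coded."""
    cov: dict[str, float] = {
        "sex": coding.sex[profile.sex],
        "age": float(profile.age),
    }
    for name in CATEGORICAL_FACTORS:
        cov[name] = sum(
            p * coding.code(name, cat) for cat, p in profile.factors[name].items()
        )
    return cov


def transition_probability(
    eq: LogisticRiskEquation, covariates: dict[str, float]
) -> float:
    """Inverse-logit of the equation's linear predictor; strictly in (0, 1)."""
    lp = eq.linear_predictor(covariates)
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)


def apply_intervention(
    baseline: RiskFactorProfile, effect: InterventionEffect
) -> RiskFactorProfile:
    """Profile after the lifestyle change takes full effect (starting year)."""
    out = baseline
    f = min(max(effect.weight_reduction_fraction, 0.0), 1.0)
    if f > 0:
        bmi = dict(baseline.factors["bmi"])
        obese, over = bmi.get("obese", 0.0), bmi.get("overweight", 0.0)
        bmi["obese"] = obese * (1 - f)
        bmi["overweight"] = over * (1 - f) + obese * f
        bmi["normal"] = bmi.get("normal", 0.0) + over * f
        out = out.replace_factor("bmi", bmi)
    if effect.pa_target is not None:
        out = out.replace_factor("physical_activity", dict(effect.pa_target))
    if effect.nutrition_target is not None:
        out = out.replace_factor("nutrition", dict(effect.nutrition_target))
    return out


def decay_weight(cycle: float, duration: float) -> float:
    """Linear fade of the intervention effect: 1 at cycle 1, 0 from cycle duration+1."""
    if cycle < 1:
        raise ValueError("cycle counts from 1")
    return min(1.0, max(0.0, (duration + 1.0 - cycle) / duration))


def decayed_profile(
    baseline: RiskFactorProfile,
    intervened: RiskFactorProfile,
    cycle: float,
    duration: float,
) -> RiskFactorProfile:
    """Blend baseline and intervened profiles with the decay weight at ``cycle``."""
    w = decay_weight(cycle, duration)
    if w == 0.0:
        return baseline
    if w == 1.0:
        return intervened
    out = baseline
    for name in CATEGORICAL_FACTORS:
        b, i = baseline.factors[name], intervened.factors[name]
        cats = set(b) | set(i)
        blended = {c: b.get(c, 0.0) + w * (i.get(c, 0.0) - b.get(c, 0.0)) for c in cats}
        out = out.replace_factor(name, blended)
    return out
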
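"""Synthetic stand-ins for inputs that are not published.

Two generators: a Gompertz–Makeham mortality table shaped like Swedish
period life tables of the 2000s (the model only needs age-banded annual
death probabilities plus the T2D cause-specific component), and an
individual-level cohort sampler that draws categorical risk-factor profiles
from the population marginals — used by the microsimulation oracle that
cross-checks the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MortalityTable
from .params import load_yaml_resource
from .risk import CATEGORICAL_FACTORS, RiskFactorProfile

__all__ = [
    "MortalityGeneratorParams",
    "generate_mortality_table",
    "life_expectancy",
    "sample_cohort",
]


@dataclass(frozen=True)
class MortalityGeneratorParams:
    """Gompertz–Makeham hazard ``makeham + b·exp(c·age)`` plus T2D cause shares.

    ``t2d_fraction`` maps age-band lower bounds to the share of all-cause
    deaths attributed to T2D; the step function is evaluated at band
    midpoints.
    """

    makeham: float = 3.0e-4
    gompertz_b: float = 2.5e-5
    gompertz_c: float = 0.095
    t2d_fraction: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.0, 30.0: 0.005, 45.0: 0.015, 65.0: 0.025}
    )
    max_age: float = 110.0
    band_width: float = 5.0

    def __post_init__(self) -> None:
        if self.gompertz_b < 0 or self.makeham < 0:
            raise ValueError("hazard components must be non-negative")
        if self.band_width <= 0 or self.max_age <= self.band_width:
            raise ValueError("invalid band layout")

    @classmethod
    def default(cls) -> "MortalityGeneratorParams":
        raw = load_yaml_resource("mortality_params.yaml")
        return cls(
            makeham=float(raw["makeham"]),
            gompertz_b=float(raw["gompertz_b"]),
            gompertz_c=float(raw["gompertz_c"]),
            t2d_fraction={float(k): float(v) for k, v in raw["t2d_fraction"].items()},
            max_age=float(raw["max_age"]),
            band_width=float(raw["band_width"]),
        )

    def hazard(self, age: float) -> float:
        return self.makeham + self.gompertz_b * np.exp(self.gompertz_c * age)

    def fraction_at(self, age: float) -> float:
        cuts = sorted(self.t2d_fraction)
        frac = 0.0
        for lo in cuts:
            if age >= lo:
                frac = self.t2d_fraction[lo]
        return frac


def generate_mortality_table(
    params: MortalityGeneratorParams | None = None,
) -> MortalityTable:
    """Deterministic age-banded mortality table from the hazard parameters.

    Annual probability per band is ``1 - exp(-hazard(midpoint))``, capped at
    1; the T2D-specific column is the cause fraction times the all-cause
    probability.
    """
    p = params or MortalityGeneratorParams.default()
    bands = []
    lo = 0.0
    while lo < p.max_age:
        hi = min(lo + p.band_width, p.max_age)
        mid = (lo + hi) / 2.0
        q_all = min(1.0, 1.0 - float(np.exp(-p.hazard(mid))))
        q_t2d = p.fraction_at(mid) * q_all
        bands.append((lo, hi, q_all, q_t2d))
        lo = hi
    return MortalityTable(bands=tuple(bands))


def life_expectancy(table: MortalityTable, from_age: float) -> float:
    """Remaining life expectancy by summing the annual survival curve.

    Discrete convention: each year survived contributes one year, with the
    final partial year approximated by half a cycle.
    """
    survival = 1.0
    total = 0.0
    age = from_age
    while age < table.max_age and survival > 1e-12:
        q_all, _ = table.lookup(age)
        deaths = survival * q_all
        total += survival - deaths / 2.0
        survival -= deaths
        age += 1.0
    return total


def sample_cohort(
    n: int,
    marginals: RiskFactorProfile,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw ``n`` individuals with independent categorical factors.

    Each factor is sampled independently from its marginal distribution (the
    published tables give no joint distribution).  Returns one row per
    individual with category labels, plus the scalar sex and age.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data: dict[str, np.ndarray] = {}
    for name in CATEGORICAL_FACTORS:
        cats = list(marginals.factors[name])
        probs = np.array([marginals.factors[name][c] for c in cats])
        probs = probs / probs.sum()
        idx = rng.choice(len(cats), size=n, p=probs)
        data[name] = np.array(cats, dtype=object)[idx]
    df = pd.DataFrame(data)
    df.insert(0, "sex", marginals.sex)
    df.insert(1, "age", marginals.age)
    return df
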
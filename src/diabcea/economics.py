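"""Utilities, costs, discounting and incremental cost-effectiveness.

Costs follow the societal perspective: the annual cost of manifest type 2
diabetes is the direct care cost grossed up by the indirect share
(``direct / (1 - indirect_share)``), each pre-diabetic state costs a fixed
share of the T2D total, and the healthy state costs nothing.  Health
utility weights (HUWs) come from an SF-6D-based table anchored at ages
30/50/70 and are interpolated linearly in attained age (clamped outside
the anchor range).  Intervention-arm HUWs fade back to the control values
with the same linear decay as the risk-factor effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .states import GlucoseState

__all__ = [
    "UtilityTable",
    "CostSchedule",
    "CEAResult",
    "t2d_total_cost",
    "prediabetes_cost",
    "discount",
    "icer",
]

_ANCHOR_AGES = (30, 50, 70)


def t2d_total_cost(direct: float, indirect_share: float) -> float:
    """Total annual T2D cost from the direct cost and the indirect share of total."""
    if not 0.0 <= indirect_share < 1.0:
        raise ValueError("indirect_share must be in [0, 1)")
    return direct / (1.0 - indirect_share)


def prediabetes_cost(t2d_total: float, share: float) -> float:
    """Annual cost of each pre-diabetic state as a share of the T2D total."""
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must be in [0, 1]")
    return share * t2d_total


def discount(amount: float, cycle: int, rate: float) -> float:
    """Present value of ``amount`` accruing in model year ``cycle`` (year 0 undiscounted)."""
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    return amount / (1.0 + rate) ** cycle


@dataclass(frozen=True)
class UtilityTable:
    """HUW lookup keyed by (sex, anchor age, arm, state); DEAD is 0."""

    values: dict[tuple[str, int, str, GlucoseState], float]

    def __post_init__(self) -> None:
        for key, huw in self.values.items():
            if not 0.0 <= huw <= 1.0:
                raise ValueError(f"HUW out of [0, 1] at {key}")

    def anchor(self, sex: str, age: int, arm: str, state: GlucoseState) -> float:
        if state is GlucoseState.DEAD:
            return 0.0
        return self.values[(sex, age, arm, state)]

    def _interpolated(self, sex: str, age: float, arm: str, state: GlucoseState) -> float:
        a = min(max(age, _ANCHOR_AGES[0]), _ANCHOR_AGES[-1])
        for lo, hi in zip(_ANCHOR_AGES, _ANCHOR_AGES[1:]):
            if a <= hi:
                u_lo = self.anchor(sex, lo, arm, state)
                u_hi = self.anchor(sex, hi, arm, state)
                return u_lo + (u_hi - u_lo) * (a - lo) / (hi - lo)
        raise AssertionError("unreachable")

    def utility_at(
        self,
        sex: str,
        age: float,
        arm: str,
        state: GlucoseState,
        decay_w: float = 0.0,
    ) -> float:
        """HUW at an attained age, age-interpolated; intervention blended by ``decay_w``.

        ``decay_w`` is the same linear fade weight applied to the risk-factor
        effect: 1 means the full intervention-arm value, 0 the control value.
        Control-arm lookups ignore it.
        """
        if state is GlucoseState.DEAD:
            return 0.0
        u_ctrl = self._interpolated(sex, age, "control", state)
        if arm == "control" or decay_w == 0.0:
            return u_ctrl
        u_int = self._interpolated(sex, age, "intervention", state)
        return u_ctrl + decay_w * (u_int - u_ctrl)

    def shifted(self, deltas: dict[GlucoseState, float]) -> "UtilityTable":
        """Table with per-state additive shifts, clamped to [0, 1] (PSA draws)."""
        values = {
            key: min(1.0, max(0.0, huw + deltas.get(key[3], 0.0)))
            for key, huw in self.values.items()
        }
        return UtilityTable(values=values)


@dataclass(frozen=True)
class CostSchedule:
    """Annual state costs and the intervention cost stream, in euros."""

    t2d_direct: float = 3602.00
    indirect_share: float = 0.57
    prediabetes_share: float = 0.46
    intervention_first_year: float = 390.43
    intervention_followup: float = 189.93
    intervention_years: int = 5
    #: override for the T2D total (PSA draw); derived from direct cost if None
    t2d_total_override: float | None = None

    @property
    def t2d_total(self) -> float:
        if self.t2d_total_override is not None:
            return self.t2d_total_override
        return t2d_total_cost(self.t2d_direct, self.indirect_share)

    @property
    def t2d_indirect(self) -> float:
        return self.t2d_total - self.t2d_direct

    @property
    def prediabetes(self) -> float:
        return prediabetes_cost(self.t2d_total, self.prediabetes_share)

    def state_costs(self, multiplier: float = 1.0) -> dict[GlucoseState, float]:
        pre = self.prediabetes * multiplier
        return {
            GlucoseState.NGT: 0.0,
            GlucoseState.IFG: pre,
            GlucoseState.IGT: pre,
            GlucoseState.IFG_IGT: pre,
            GlucoseState.T2D: self.t2d_total * multiplier,
            GlucoseState.DEAD: 0.0,
        }

    def intervention_cost(self, cycle: int, multiplier: float = 1.0) -> float:
        """Per-person programme cost in model year ``cycle`` (0-based; year 0 = year one)."""
        if cycle == 0:
            return self.intervention_first_year * multiplier
        if 1 <= cycle < self.intervention_years:
            return self.intervention_followup * multiplier
        return 0.0

    def scaled(self, factor: float) -> "CostSchedule":
        """All state and intervention costs multiplied by ``factor`` (±10% sensitivity)."""
        return replace(
            self,
            t2d_direct=self.t2d_direct * factor,
            intervention_first_year=self.intervention_first_year * factor,
            intervention_followup=self.intervention_followup * factor,
            t2d_total_override=(
                None
                if self.t2d_total_override is None
                else self.t2d_total_override * factor
            ),
        )


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance flag.

    Returns Δcost/ΔQALY when the intervention gains QALYs at extra (or zero)
    cost; ``"dominant"`` when it gains QALYs and saves money; ``"dominated"``
    when it loses QALYs at extra cost.
    """
    if delta_qaly > 0:
        if delta_cost < 0:
            return "dominant"
        return delta_cost / delta_qaly
    if delta_qaly < 0:
        if delta_cost > 0:
            return "dominated"
        return delta_cost / delta_qaly
    return "dominated" if delta_cost > 0 else "dominant"


@dataclass(frozen=True)
class CEAResult:
    """Per-arm discounted totals and the incremental comparison."""

    cost_control: float
    qaly_control: float
    cost_intervention: float
    qaly_intervention: float

    @property
    def delta_cost(self) -> float:
        return self.cost_intervention - self.cost_control

    @property
    def delta_qaly(self) -> float:
        return self.qaly_intervention - self.qaly_control

    @property
    def icer(self) -> float | str:
        return icer(self.delta_cost, self.delta_qaly)

    def to_dict(self) -> dict:
        value = self.icer
        return {
            "cost_control": self.cost_control,
            "qaly_control": self.qaly_control,
            "cost_intervention": self.cost_intervention,
            "qaly_intervention": self.qaly_intervention,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": value if isinstance(value, str) else float(value),
        }
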
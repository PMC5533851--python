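"""Probabilistic sensitivity analysis.

Parameter uncertainty is propagated by Monte Carlo: transition
probabilities and health utility weights are drawn from beta distributions
and cost parameters from gamma distributions, all parameterized by the
method of moments.  Cost standard deviations equal their means (the
exponential special case of the gamma); the spread of probabilities and
utilities is a configurable coefficient of variation, since the source
regressions' standard errors are not published.  Each replicate uses one
parameter draw for both arms (common random numbers), runs both cohorts and
records the incremental (Δcost, ΔQALY) pair.  Summaries use ordered-value
percentile intervals; cost-effectiveness acceptability is the fraction of
replicates with positive net monetary benefit at a willingness-to-pay
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import ScenarioConfig, run_cohort
from .economics import icer
from .risk import apply_intervention, expected_covariates, transition_probability
from .states import GlucoseState, LIVING_STATES

__all__ = [
    "DistributionSpec",
    "PSAResult",
    "beta_from_moments",
    "gamma_from_moments",
    "percentile_interval",
    "ceac",
    "run_psa",
    "ce_plane_table",
]


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(alpha, beta) of the beta distribution with the given mean and SD."""
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must be in (0, 1)")
    var = sd * sd
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError(f"infeasible beta moments: mean={mean}, sd={sd}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(shape, scale) of the gamma distribution with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma moments must be positive")
    return mean * mean / (sd * sd), sd * sd / mean


@dataclass(frozen=True)
class DistributionSpec:
    """A parameter's sampling distribution, specified by its first two moments.

    ``degenerate`` always returns the mean; infeasible beta moments fall
    back to degenerate with a warning rather than aborting a replicate set.
    """

    family: str  # beta | gamma | degenerate
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "degenerate"):
            raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "degenerate" or self.sd == 0.0:
            return self.mean if size is None else np.full(size, self.mean)
        if self.family == "beta":
            try:
                a, b = beta_from_moments(self.mean, self.sd)
            except ValueError:
                warnings.warn(
                    f"infeasible beta moments (mean={self.mean}, sd={self.sd}); "
                    "using the mean",
                    RuntimeWarning,
                )
                return self.mean if size is None else np.full(size, self.mean)
            return rng.beta(a, b, size=size)
        shape, scale = gamma_from_moments(self.mean, self.sd)
        return rng.gamma(shape, scale, size=size)


def percentile_interval(
    samples, lower: float = 0.025, upper: float = 0.975
) -> tuple[float, float]:
    """Ordered-value interval: 1-based ranks ``ceil(n*lower)`` and ``ceil(n*upper)``."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples")
    lo = max(1, math.ceil(n * lower))
    hi = max(1, math.ceil(n * upper))
    return float(x[lo - 1]), float(x[hi - 1])


@dataclass(frozen=True)
class PSAResult:
    """Replicate-level incremental outcomes of one scenario's PSA."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return int(self.delta_cost.size)

    def summary(self) -> dict:
        dc, dq = self.delta_cost, self.delta_qaly
        mean_icer = icer(float(dc.mean()), float(dq.mean()))
        return {
            "n": self.n,
            "delta_cost_mean": float(dc.mean()),
            "delta_cost_median": float(np.median(dc)),
            "delta_cost_interval": percentile_interval(dc),
            "delta_qaly_mean": float(dq.mean()),
            "delta_qaly_median": float(np.median(dq)),
            "delta_qaly_interval": percentile_interval(dq),
            "icer_of_means": mean_icer if isinstance(mean_icer, str) else float(mean_icer),
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_qaly": self.delta_qaly, "delta_cost": self.delta_cost}
        )


def ceac(result: PSAResult, thresholds) -> np.ndarray:
    """P(cost-effective) at each threshold: fraction with λ·ΔQALY − Δcost > 0."""
    lam = np.asarray(thresholds, dtype=float)
    if np.any(lam < 0):
        raise ValueError("thresholds must be non-negative")
    nmb = lam[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


def ce_plane_table(result: PSAResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scatter table of (ΔQALY, Δcost) pairs plus counts per CE-plane quadrant."""
    df = result.to_frame()
    counts = {
        "northeast": int(((result.delta_qaly > 0) & (result.delta_cost >= 0)).sum()),
        "southeast": int(((result.delta_qaly > 0) & (result.delta_cost < 0)).sum()),
        "northwest": int(((result.delta_qaly <= 0) & (result.delta_cost >= 0)).sum()),
        "southwest": int(((result.delta_qaly <= 0) & (result.delta_cost < 0)).sum()),
    }
    return df, counts


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _replicate_parameters(params, config: ScenarioConfig, prob_cv: float, huw_cv: float):
    """Precompute the per-replicate sampling specs for one scenario.

    Transition draws act as logit-scale intercept shifts anchored at each
    equation's probability evaluated at the baseline covariates and the
    starting age; HUW draws act as additive per-state shifts anchored at
    the control-arm starting values.  Anchors are deterministic, so the same
    specs serve every replicate.
    """
    baseline = params.baseline_profile(config.sex, config.start_age)
    cov = expected_covariates(baseline, params.coding)
    eq_specs = []
    for eq in params.equations:
        p0 = transition_probability(eq, cov)
        spec = DistributionSpec("beta", p0, prob_cv * p0) if prob_cv > 0 else DistributionSpec("degenerate", p0)
        eq_specs.append((eq, p0, spec))
    huw_specs = []
    for s in LIVING_STATES:
        u0 = params.utilities.utility_at(config.sex, config.start_age, "control", s)
        spec = DistributionSpec("beta", u0, huw_cv * u0) if huw_cv > 0 else DistributionSpec("degenerate", u0)
        huw_specs.append((s, u0, spec))
    c = params.costs
    cost_specs = {
        "t2d_total": DistributionSpec("gamma", c.t2d_total, c.t2d_total),
        "iv_first": DistributionSpec("gamma", c.intervention_first_year, c.intervention_first_year),
        "iv_follow": DistributionSpec("gamma", c.intervention_followup, c.intervention_followup),
    }
    return eq_specs, huw_specs, cost_specs


def _draw_params(params, eq_specs, huw_specs, cost_specs, rng, cost_sd_equals_mean: bool):
    equations = []
    for eq, p0, spec in eq_specs:
        p = float(spec.sample(rng))
        p = min(max(p, 1e-12), 1.0 - 1e-12)
        shift = _logit(p) - _logit(p0)
        equations.append(replace(eq, intercept=eq.intercept + shift))
    deltas = {}
    for s, u0, spec in huw_specs:
        deltas[s] = float(spec.sample(rng)) - u0
    utilities = params.utilities.shifted(deltas)
    if cost_sd_equals_mean:
        costs = replace(
            params.costs,
            t2d_total_override=float(cost_specs["t2d_total"].sample(rng)),
            intervention_first_year=float(cost_specs["iv_first"].sample(rng)),
            intervention_followup=float(cost_specs["iv_follow"].sample(rng)),
        )
    else:
        costs = params.costs
    return replace(params, equations=equations, utilities=utilities, costs=costs)


def run_psa(
    config: ScenarioConfig,
    params,
    n: int = 1000,
    seed: int = 0,
    prob_cv: float = 0.10,
    huw_cv: float = 0.05,
    cost_sd_equals_mean: bool = True,
) -> PSAResult:
    """Monte-Carlo PSA of one sex×age scenario.

    Each replicate draws one full parameter set, runs control and
    intervention cohorts on it, and records discounted (Δcost, ΔQALY).
    Setting ``prob_cv`` and ``huw_cv`` to 0 and ``cost_sd_equals_mean`` to
    False collapses every replicate to the deterministic result.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    eq_specs, huw_specs, cost_specs = _replicate_parameters(
        params, config, prob_cv, huw_cv
    )
    delta_cost = np.empty(n)
    delta_qaly = np.empty(n)
    cfg_control = replace(config, arm="control", renormalize_exits=True)
    cfg_intervention = replace(config, arm="intervention", renormalize_exits=True)
    for k in range(n):
        p_k = _draw_params(params, eq_specs, huw_specs, cost_specs, rng, cost_sd_equals_mean)
        control = run_cohort(cfg_control, p_k)
        intervention = run_cohort(cfg_intervention, p_k)
        delta_cost[k] = intervention.total_cost - control.total_cost
        delta_qaly[k] = intervention.total_qaly - control.total_qaly
    return PSAResult(delta_cost=delta_cost, delta_qaly=delta_qaly, seed=seed)
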
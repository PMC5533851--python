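"""Scenario orchestration: the six sex×age runs and the sensitivity suite.

The base case evaluates men and women starting at ages 30, 50 and 70, each
deterministically (point estimates of every parameter) and probabilistically
(Monte-Carlo PSA).  The sensitivity suite re-runs all six scenarios
deterministically under structural and parameter variations: removing the
T2D→pre-diabetic reversion, scaling all costs by ±10%, doubling the effect
duration to 14 years, and weakening the weight reduction to 3.3% (with and
without the physical-activity and diet effects).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import ScenarioConfig, run_cea
from .economics import CEAResult
from .params import ModelParameters
from .psa import PSAResult, ceac, ce_plane_table, run_psa
from .risk import InterventionEffect

__all__ = ["SCENARIOS", "RunManifest", "run_all_scenarios", "run_sensitivity_suite"]

logger = logging.getLogger("diabcea")

#: The six base-case scenarios: (sex, starting age).
SCENARIOS = tuple(
    (sex, age) for sex in ("male", "female") for age in (30.0, 50.0, 70.0)
)

#: Default CEAC threshold grid (€ per QALY).
CEAC_THRESHOLDS = tuple(range(0, 100001, 2500))


def _scenario_name(sex: str, age: float) -> str:
    return f"{sex}_{int(age)}"


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of one orchestrated run: inputs digest, seed, and results.

    ``results`` maps ``variant/scenario`` names to plain dictionaries
    (deterministic CEA fields, and PSA summaries where run); ``files`` lists
    every artifact written.  Re-running with the same seed and inputs
    reproduces identical results and hash.
    """

    seed: int
    config_hash: str
    version: str
    results: dict[str, dict] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def _params_digest(params: ModelParameters) -> dict:
    return {
        "equations": [
            (e.source.name, e.target.name, e.intercept, sorted(e.coefficients.items()))
            for e in params.equations
        ],
        "baseline": params.baseline_factors,
        "starting": {s.name: v for s, v in params.starting_distribution.items()},
        "costs": str(params.costs),
        "effect": str(params.effect),
        "mortality": list(params.mortality.bands),
        "t2d_prevalence": params.t2d_prevalence,
    }


def run_all_scenarios(
    params: ModelParameters | None = None,
    out_dir: str | Path | None = None,
    n_psa: int = 1000,
    seed: int = 0,
    make_plots: bool = False,
    discount_rate: float = 0.03,
) -> RunManifest:
    """Deterministic and (if ``n_psa`` > 0) probabilistic results for all six scenarios.

    Writes tidy CSV tables of the deterministic cost/QALY/ICER results and,
    per scenario, the PSA replicates, summary and CEAC; returns a manifest.
    """
    params = params or ModelParameters.default()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=seed,
        config_hash=_config_hash(
            {"params": _params_digest(params), "n_psa": n_psa, "seed": seed}
        ),
        version=__version__,
    )
    det_rows = []
    psa_rows = []
    for i, (sex, age) in enumerate(SCENARIOS):
        name = _scenario_name(sex, age)
        t0 = time.perf_counter()
        config = ScenarioConfig(sex=sex, start_age=age, discount_rate=discount_rate)
        cea = run_cea(config, params)
        entry = cea.to_dict()
        det_rows.append({"scenario": name, "sex": sex, "age": int(age), **entry})

        if n_psa > 0:
            psa_seed = (seed * 1009 + i) % (2**31)
            psa = run_psa(config, params, n=n_psa, seed=psa_seed)
            summary = psa.summary()
            entry["psa"] = summary
            psa_rows.append({"scenario": name, **_flatten_summary(summary)})
            probs = ceac(psa, CEAC_THRESHOLDS)
            if out is not None:
                psa.to_frame().to_csv(out / f"psa_{name}.csv", index=False)
                pd.DataFrame(
                    {"threshold": CEAC_THRESHOLDS, "p_cost_effective": probs}
                ).to_csv(out / f"ceac_{name}.csv", index=False)
                manifest.files += [f"psa_{name}.csv", f"ceac_{name}.csv"]
                if make_plots:
                    from .plotting import plot_ce_plane, plot_ceac

                    plot_ce_plane(psa, title=name).savefig(out / f"ce_plane_{name}.png")
                    plot_ceac(CEAC_THRESHOLDS, probs, title=name).savefig(
                        out / f"ceac_{name}.png"
                    )
                    manifest.files += [f"ce_plane_{name}.png", f"ceac_{name}.png"]
        manifest.results[name] = entry
        logger.info("scenario %s done in %.2f s", name, time.perf_counter() - t0)

    if out is not None:
        pd.DataFrame(det_rows).to_csv(out / "deterministic.csv", index=False)
        manifest.files.append("deterministic.csv")
        if psa_rows:
            pd.DataFrame(psa_rows).to_csv(out / "probabilistic.csv", index=False)
            manifest.files.append("probabilistic.csv")
        manifest.to_json(out / "manifest.json")
    return manifest


def _flatten_summary(summary: dict) -> dict:
    flat = {}
    for k, v in summary.items():
        if isinstance(v, tuple | list):
            flat[f"{k}_low"], flat[f"{k}_high"] = v
        else:
            flat[k] = v
    return flat


def _sensitivity_variants(params: ModelParameters) -> dict[str, tuple[ModelParameters, dict]]:
    """Variant id → (parameter set, extra ScenarioConfig fields)."""
    base_effect = params.effect
    return {
        "no_t2d_reversion": (params, {"disable_t2d_reversion": True}),
        "costs_plus_10pct": (
            params,
            {"state_cost_multiplier": 1.1, "intervention_cost_multiplier": 1.1},
        ),
        "costs_minus_10pct": (
            params,
            {"state_cost_multiplier": 0.9, "intervention_cost_multiplier": 0.9},
        ),
        "effect_14_years": (
            params.with_effect(replace(base_effect, effect_duration=14.0)),
            {},
        ),
        "weight_loss_3.3pct": (
            params.with_effect(replace(base_effect, weight_reduction_fraction=0.033)),
            {},
        ),
        "weight_loss_3.3pct_only": (
            params.with_effect(
                InterventionEffect(
                    weight_reduction_fraction=0.033,
                    pa_target=None,
                    nutrition_target=None,
                    effect_duration=base_effect.effect_duration,
                )
            ),
            {},
        ),
    }


def run_sensitivity_suite(
    params: ModelParameters | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    variants: list[str] | None = None,
    discount_rate: float = 0.03,
) -> RunManifest:
    """Deterministic sensitivity analyses over all six scenarios.

    ``variants`` selects a subset by id; unknown ids raise.  (The
    probabilistic analysis itself is :func:`run_all_scenarios` with
    ``n_psa`` > 0.)
    """
    params = params or ModelParameters.default()
    all_variants = _sensitivity_variants(params)
    if variants is None:
        variants = list(all_variants)
    unknown = set(variants) - set(all_variants)
    if unknown:
        raise ValueError(f"unknown sensitivity variant(s): {sorted(unknown)}")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=seed,
        config_hash=_config_hash(
            {"params": _params_digest(params), "variants": variants, "seed": seed}
        ),
        version=__version__,
    )
    for vid in variants:
        v_params, extra = all_variants[vid]
        rows = []
        for sex, age in SCENARIOS:
            name = _scenario_name(sex, age)
            config = ScenarioConfig(
                sex=sex, start_age=age, discount_rate=discount_rate, **extra
            )
            cea = run_cea(config, v_params)
            entry = cea.to_dict()
            # echo of the parameters this variant actually used
            entry["variant"] = vid
            entry["config"] = dict(extra)
            entry["state_costs"] = {
                s.name: c
                for s, c in v_params.costs.state_costs(
                    extra.get("state_cost_multiplier", 1.0)
                ).items()
            }
            entry["intervention_costs"] = [
                v_params.costs.intervention_cost(
                    t, extra.get("intervention_cost_multiplier", 1.0)
                )
                for t in range(v_params.costs.intervention_years)
            ]
            entry["effect"] = str(v_params.effect)
            manifest.results[f"{vid}/{name}"] = entry
            rows.append({"scenario": name, "sex": sex, "age": int(age), **cea.to_dict()})
        if out is not None:
            fname = f"sensitivity_{vid.replace('.', '_')}.csv"
            pd.DataFrame(rows).to_csv(out / fname, index=False)
            manifest.files.append(fname)
        logger.info("sensitivity variant %s done", vid)
    if out is not None:
        manifest.to_json(out / "sensitivity_manifest.json")
    return manifest
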
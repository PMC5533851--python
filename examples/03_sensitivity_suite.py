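"""Deterministic sensitivity analyses across all six sex×age scenarios.

Each variant changes one assumption — no reversion from diabetes, costs
±10%, a 14-year effect, or a weaker 3.3% weight loss (alone or with the
activity/diet effects) — and reports how the ICER responds.
"""

from diabcea import ModelParameters, run_sensitivity_suite

params = ModelParameters.default()
manifest = run_sensitivity_suite(params)

print(f"{'variant/scenario':38s} {'Δcost (€)':>10s} {'ΔQALY':>8s} {'ICER (€/QALY)':>14s}")
for name, entry in manifest.results.items():
    icer = entry["icer"]
    icer_txt = f"{icer:,.0f}" if not isinstance(icer, str) else icer
    print(f"{name:38s} {entry['delta_cost']:10.1f} {entry['delta_qaly']:8.4f} {icer_txt:>14s}")
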
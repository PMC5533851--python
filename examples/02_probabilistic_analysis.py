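"""Probabilistic sensitivity analysis of the male/70 scenario.

Draws 1000 parameter sets (beta for probabilities and utilities, gamma with
SD = mean for costs), runs both arms per draw, and summarizes the
incremental cost and QALY distributions.  The CEAC value is the share of
replicates whose net monetary benefit at 50,000 €/QALY is positive — the
probability that the programme is cost-effective at that threshold.
"""

from diabcea import ModelParameters, ScenarioConfig, ce_plane_table, ceac, run_psa

params = ModelParameters.default()
psa = run_psa(ScenarioConfig(sex="male", start_age=70), params, n=1000, seed=1)

s = psa.summary()
print(f"mean Δcost  {s['delta_cost_mean']:8.1f} €   "
      f"95% interval [{s['delta_cost_interval'][0]:.0f}; {s['delta_cost_interval'][1]:.0f}]")
print(f"mean ΔQALY  {s['delta_qaly_mean']:8.4f}     "
      f"95% interval [{s['delta_qaly_interval'][0]:.4f}; {s['delta_qaly_interval'][1]:.4f}]")
print(f"ICER of means: {s['icer_of_means']:,.0f} €/QALY")
print(f"P(cost-effective at 50,000 €/QALY): {float(ceac(psa, [50_000])[0]):.3f}")

_, quadrants = ce_plane_table(psa)
print("CE-plane quadrants:", quadrants)
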
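# Risk-factor distribution of the pre-diabetic population at first
# examination (percent shares converted to proportions), and the target
# distributions reached by the lifestyle intervention in its starting year.
# Note: the published no-intervention physical-activity column sums to 104%
# (9.7 + 68.4 + 25.9); it is renormalized to 1 on load.
baseline:
  education: {high: 0.255, middle: 0.538, low: 0.207}
  triglyceride: {normal: 0.712, high: 0.288}
  blood_pressure: {normal: 0.650, high: 0.350}
  bmi: {underweight: 0.005, normal: 0.388, overweight: 0.439, obese: 0.168}
  smoking: {never: 0.434, formerly: 0.311, present: 0.255}
  physical_activity: {active: 0.097, moderately: 0.684, sedentary: 0.259}
  snus: {none: 0.876, up_to_4_cans: 0.093, over_4_cans: 0.031}
  nutrition: {at_least_5_a_day: 0.092, less_than_5_a_day: 0.908}
  marital_status: {partnership: 0.841, single: 0.159}
  family_history: {"no": 0.774, "yes": 0.226}
  self_perceived_health: {good: 0.738, bad: 0.262}
intervention_targets:
  physical_activity: {active: 0.186, moderately: 0.624, sedentary: 0.190}
  nutrition: {at_least_5_a_day: 0.183, less_than_5_a_day: 0.817}
# Starting occupancy over the pre-diabetic states (IFG / IGT / IFG&IGT).
starting_distribution:
  IFG: 0.662
  IGT: 0.272
  IFG_IGT: 0.066
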
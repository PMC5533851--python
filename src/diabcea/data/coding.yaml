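# Numeric coding of categorical covariates entering the risk equations.
# The source regressions use a single coefficient per factor, implying a
# scalar code per category.  Convention here: binary factors 0/1 with the
# lowest-risk level at 0; three-level factors coded ordinally 0/1/2; BMI
# collapses underweight+normal to 0 (overweight 1, obese 2).  Sex is coded
# male 0 / female 1.  Edit this file to explore alternative codings.
sex:
  male: 0
  female: 1
education:
  high: 0
  middle: 1
  low: 2
triglyceride:
  normal: 0
  high: 1
blood_pressure:
  normal: 0
  high: 1
bmi:
  underweight: 0
  normal: 0
  overweight: 1
  obese: 2
smoking:
  never: 0
  formerly: 1
  present: 2
physical_activity:
  active: 0
  moderately: 1
  sedentary: 2
snus:
  none: 0
  up_to_4_cans: 1
  over_4_cans: 2
nutrition:
  at_least_5_a_day: 0
  less_than_5_a_day: 1
marital_status:
  partnership: 0
  single: 1
family_history:
  "no": 0
  "yes": 1
self_perceived_health:
  good: 0
  bad: 1
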
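# Logistic risk equations for annual transitions between glucose states,
# estimated on the Västerbotten Intervention Program cohort (published
# regression table, transcribed as data).  logit P = intercept + sum(coef * covariate),
# covariates coded per coding.yaml.  Twelve equations: three exits from NGT,
# three reversions to NGT, three progressions to T2D, three reversions from T2D.
equations:
  - from: NGT
    to: IFG
    intercept: -3.07
    coefficients:
      sex: -0.29
      age: 0.01
      education: 0.11
      family_history: 0.19
      snus: -0.09
      triglyceride: 0.15
      blood_pressure: 0.12
      bmi: 0.16
      smoking: 0.23
  - from: NGT
    to: IGT
    intercept: -7.29
    coefficients:
      sex: 0.51
      age: 0.06
      education: 0.09
      physical_activity: 0.14
      family_history: 0.15
      triglyceride: 0.41
      blood_pressure: 0.34
      bmi: 0.21
      smoking: -0.12
  - from: NGT
    to: IFG_IGT
    intercept: -6.20
    coefficients:
      sex: -0.16
      age: 0.04
      snus: -0.24
      family_history: 0.32
      physical_activity: 0.15
      triglyceride: 0.20
      blood_pressure: 0.60
      bmi: 0.50
      nutrition: -0.33
  - from: IFG
    to: NGT
    intercept: 2.84
    coefficients:
      family_history: -0.43
      age: -0.02
      education: -0.23
      blood_pressure: -0.25
      bmi: -0.38
      triglyceride: -0.26
  - from: IGT
    to: NGT
    intercept: 3.06
    coefficients:
      sex: 0.72
      age: -0.07
      education: -0.23
      bmi: -0.37
      self_perceived_health: -0.29
      triglyceride: -0.49
  - from: IFG_IGT
    to: NGT
    intercept: -0.61
    coefficients:
      sex: 0.81
      snus: 1.15
      smoking: -1.24
      bmi: -0.77
  - from: IFG
    to: T2D
    intercept: -6.98
    coefficients:
      sex: -0.44
      age: 0.05
      family_history: 0.48
      marital_status: 0.36
      nutrition: 0.51
      triglyceride: 0.30
      blood_pressure: 0.61
      bmi: 0.57
  - from: IGT
    to: T2D
    intercept: -6.54
    coefficients:
      sex: -0.75
      age: 0.07
      nutrition: 0.87
      bmi: 0.35
      blood_pressure: 0.35
      triglyceride: 0.56
  - from: IFG_IGT
    to: T2D
    intercept: -0.55
    coefficients:
      sex: -0.61
      bmi: 0.71
      family_history: 0.87
      nutrition: -1.06
      smoking: 0.42
  - from: T2D
    to: IFG
    intercept: -0.34
    coefficients:
      bmi: -0.57
      blood_pressure: -0.68
      smoking: -0.385
  - from: T2D
    to: IGT
    intercept: -3.37
    coefficients:
      family_history: -1.42
      self_perceived_health: 1.13
  - from: T2D
    to: IFG_IGT
    intercept: -6.80
    coefficients:
      sex: 1.22
      physical_activity: 1.49
      education: 0.63
      self_perceived_health: -1.07
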
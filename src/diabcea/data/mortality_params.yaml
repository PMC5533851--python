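# Default calibration of the synthetic Swedish-like mortality generator.
# Annual hazard: makeham + gompertz_b * exp(gompertz_c * age); the defaults
# are tuned so remaining life expectancy at age 30 lands near 50 years,
# the order of magnitude of Swedish period life tables for the 2000s.
# (Stand-in for the regional Statistics Sweden 2003-2009 table, which is
# not published; see docs/methods.md.)
makeham: 0.0003
gompertz_b: 2.5e-05
gompertz_c: 0.095
max_age: 110
band_width: 5
# Share of all-cause deaths attributed to T2D as underlying cause, by age
# band lower bound; roughly matches national cause-of-death proportions
# (diabetes is listed on ~2-3% of death certificates at older ages).
t2d_fraction:
  0: 0.000
  30: 0.005
  45: 0.015
  65: 0.025
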
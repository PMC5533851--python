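# Annual costs in 2007 euros, societal perspective.
# The T2D total is direct care cost grossed up for the indirect share
# (sickness absence, early retirement, production loss); each pre-diabetic
# state costs a fixed share of the T2D total; NGT and death cost nothing.
t2d_direct: 3602.00
indirect_share: 0.57        # share of T2D total that is indirect
prediabetes_share: 0.46     # pre-diabetic state cost as share of T2D total
intervention_first_year: 390.43
intervention_followup: 189.93   # years 2-5
intervention_years: 5
discount_rate: 0.03
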
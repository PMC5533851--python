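# Health utility weights (SF-6D derived) by sex, anchor age, arm and glucose
# state.  Death has utility 0 by definition and is not listed.
huw:
  male:
    30:
      control:      {NGT: 0.83, IFG: 0.82, IGT: 0.73, IFG_IGT: 0.77, T2D: 0.72}
      intervention: {NGT: 0.83, IFG: 0.82, IGT: 0.73, IFG_IGT: 0.77, T2D: 0.72}
    50:
      control:      {NGT: 0.83, IFG: 0.82, IGT: 0.72, IFG_IGT: 0.79, T2D: 0.72}
      intervention: {NGT: 0.83, IFG: 0.82, IGT: 0.72, IFG_IGT: 0.79, T2D: 0.72}
    70:
      control:      {NGT: 0.83, IFG: 0.81, IGT: 0.72, IFG_IGT: 0.81, T2D: 0.72}
      intervention: {NGT: 0.83, IFG: 0.82, IGT: 0.72, IFG_IGT: 0.81, T2D: 0.72}
  female:
    30:
      control:      {NGT: 0.80, IFG: 0.79, IGT: 0.70, IFG_IGT: 0.74, T2D: 0.68}
      intervention: {NGT: 0.80, IFG: 0.79, IGT: 0.70, IFG_IGT: 0.74, T2D: 0.68}
    50:
      control:      {NGT: 0.80, IFG: 0.79, IGT: 0.70, IFG_IGT: 0.76, T2D: 0.68}
      intervention: {NGT: 0.80, IFG: 0.79, IGT: 0.70, IFG_IGT: 0.76, T2D: 0.68}
    70:
      control:      {NGT: 0.80, IFG: 0.78, IGT: 0.69, IFG_IGT: 0.78, T2D: 0.68}
      intervention: {NGT: 0.80, IFG: 0.78, IGT: 0.69, IFG_IGT: 0.78, T2D: 0.68}
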
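# Standard Gibbs free energies of formation at 25 C (kJ/mol), with the
# element/charge composition used for reaction balance checking.
# phase: aq (activity = molar concentration), s / l (unit activity),
# conv (bookkeeping species at unit activity, e.g. the electron).
species:
  H2O:
    elements: {H: 2, O: 1}
    charge: 0
    phase: l
    dgf: -237.18
    provenance: CODATA
  H+:
    elements: {H: 1}
    charge: 1
    phase: aq
    dgf: 0.0
    provenance: convention
  e-:
    elements: {}
    charge: -1
    phase: conv
    dgf: 0.0
    provenance: convention
  acetate-:
    elements: {C: 2, H: 3, O: 2}
    charge: -1
    phase: aq
    dgf: -369.41
    provenance: Thauer-1977
  lactate-:
    elements: {C: 3, H: 5, O: 3}
    charge: -1
    phase: aq
    dgf: -517.81
    provenance: Thauer-1977
  glucose:
    elements: {C: 6, H: 12, O: 6}
    charge: 0
    phase: aq
    dgf: -917.22
    provenance: Thauer-1977
  HCO3-:
    elements: {C: 1, H: 1, O: 3}
    charge: -1
    phase: aq
    dgf: -586.85
    provenance: Thauer-1977
  SO42-:
    elements: {S: 1, O: 4}
    charge: -2
    phase: aq
    dgf: -744.63
    provenance: Thauer-1977
  HS-:
    elements: {H: 1, S: 1}
    charge: -1
    phase: aq
    dgf: 12.05
    provenance: Thauer-1977
  H2S:
    elements: {H: 2, S: 1}
    charge: 0
    phase: aq
    dgf: -27.87
    provenance: Thauer-1977
  Fe2+:
    elements: {Fe: 1}
    charge: 2
    phase: aq
    dgf: -78.90
    provenance: CODATA
  goethite:
    elements: {Fe: 1, O: 2, H: 1}
    charge: 0
    phase: s
    dgf: -488.60
    provenance: mineral-compilation
  hematite:
    elements: {Fe: 2, O: 3}
    charge: 0
    phase: s
    dgf: -742.20
    provenance: mineral-compilation
  ferrihydrite:
    elements: {Fe: 1, O: 3, H: 3}
    charge: 0
    phase: s
    dgf: -708.50
    provenance: representative 2-line ferrihydrite
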
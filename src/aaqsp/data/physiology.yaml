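# Reduced whole-body physiology of a 73 kg, 30-year-old European male.
# Volumes in L, blood flows as plasma flows in L/min.  Enzyme expression is
# relative abundance normalized to liver (= 1.0); compartments not listed
# express none of the enzyme.
body_weight: 73.0
hematocrit: 0.45
compartments:
  - {name: venous_plasma, volume: 1.8}
  - {name: arterial_plasma, volume: 1.0}
  - {name: blood_cells, volume: 2.2}
  - {name: gut_lumen, volume: 1.0}
  - {name: gut_wall, volume: 1.1, blood_flow: 0.65}
  - name: liver
    volume: 1.8
    blood_flow: 0.35   # hepatic artery; portal inflow arrives via gut_wall
    subcompartments: {vascular: 0.10, interstitial: 0.16, intracellular: 0.74}
  - {name: kidney, volume: 0.31, blood_flow: 0.66}
  - {name: periphery, volume: 36.0, blood_flow: 1.40}
enzyme_expression:
  CYP3A4: {liver: 1.0, gut_wall: 0.25}
  CYP2C9: {liver: 1.0, gut_wall: 0.05}
  CYP1A2: {liver: 1.0}
  CYP2J2: {liver: 1.0, gut_wall: 0.10}
  UGT2B7: {liver: 1.0}
  UGT1A1: {liver: 1.0}
  ADH:    {liver: 1.0}
  AADAC:  {liver: 1.0}
  OATP1B1: {liver: 1.0}
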
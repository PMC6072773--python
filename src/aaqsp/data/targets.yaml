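# Pharmacological target binding affinities (Ki, umol/L), derived from
# published IC50 values via the IC50-to-Ki conversion under unsaturated
# competitive inhibition (Ki ~ IC50 when S << Km).
celecoxib:
  - {enzyme: COX-2, ki: 0.017}
diclofenac:
  - {enzyme: COX-2, ki: 0.018}
licofelone:
  - {enzyme: COX-2, ki: 0.032}
  - {enzyme: 5-LOX, ki: 0.056}
zileuton:
  - {enzyme: 5-LOX, ki: 0.021}
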
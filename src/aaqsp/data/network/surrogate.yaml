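# Packaged surrogate network of arachidonic-acid metabolism.
#
# Reduced topology: a shared arachidonic-acid (AA) pool fed at constant
# rate is consumed by the COX-2 branch (AA -> PGH2 -> PGE2), the 5-LOX
# branch (AA -> LTA4 -> wLTB4) and a lumped "other pathways" sink; both
# terminal mediators degrade enzymatically.  Two regulatory edges represent
# feedback control: PGE2 positively feeds back on the COX-2 step and wLTB4
# negatively on the 5-LOX step.
#
# All parameters in this file are repo-defined surrogate values (umol/L,
# min), chosen so that substrate concentrations sit two to three orders of
# magnitude below Km (inhibition of COX-2 and 5-LOX operates far from
# saturation) and downstream mediator turnover half-lives are ~7 min,
# matching the minutes-scale turnover of prostaglandins and leukotrienes in
# vivo so mediator levels track the inhibition signal over the 6-h window.
# The eicosanoid branches are deliberately minor consumers of the AA pool
# (re-esterification and other oxidative routes dominate whole-cell AA
# turnover), so competitive inhibition of one branch causes only mild
# substrate shunting into the other.
species:
  - {name: AA,    initial: 0.23}
  - {name: PGH2,  initial: 0.0092}
  - {name: PGE2,  initial: 0.0092}
  - {name: LTA4,  initial: 0.0069}
  - {name: wLTB4, initial: 0.0069}
reactions:
  # 0: constant AA input flux
  - {substrate: null, product: AA, enzyme: AA-input, vmax: 0.020, km: 1.0}
  # 1: COX-2 committed step (competitively inhibitable)
  - {substrate: AA, product: PGH2, enzyme: COX-2, vmax: 0.20, km: 50.0}
  # 2: prostaglandin E synthase
  - {substrate: PGH2, product: PGE2, enzyme: PGES, vmax: 5.0, km: 50.0}
  # 3: PGE2 degradation (15-PGDH)
  - {substrate: PGE2, product: null, enzyme: PGDH, vmax: 5.0, km: 50.0}
  # 4: 5-LOX committed step (competitively inhibitable)
  - {substrate: AA, product: LTA4, enzyme: 5-LOX, vmax: 0.15, km: 50.0}
  # 5: LTA4 hydrolase + omega-oxidation to wLTB4
  - {substrate: LTA4, product: wLTB4, enzyme: LTA4H, vmax: 5.0, km: 50.0}
  # 6: wLTB4 degradation
  - {substrate: wLTB4, product: null, enzyme: LTB4-deg, vmax: 6.0, km: 60.0}
  # 7: other AA-consuming pathways (re-esterification, CYP/12-LOX lumped)
  - {substrate: AA, product: null, enzyme: AA-other, vmax: 4.0, km: 50.0}
feedback_edges:
  - {regulator: PGE2, target_reaction: 1, sign: positive, strength: 20.0}
  - {regulator: wLTB4, target_reaction: 4, sign: negative, strength: 20.0}
provenance: packaged_surrogate
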
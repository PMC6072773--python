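# Licofelone (dual COX-2/5-LOX inhibitor).  Acyl glucuronidation (UGT2B7)
# and CYP2J2 hydroxylation; hepatic uptake transport and biliary excretion
# of the parent.
name: licofelone
molecular_weight: 379.88
fraction_unbound_plasma: 0.01
partition_coefficients:
  gut_wall: 1.5
  liver: 2.5
  kidney: 1.5
  periphery: 0.760876
  blood_cells: 1.0
absorption: {ka: 0.0146838, lag: 24, formulation: dissolved}
processes:
  - kind: metabolism
    enzyme_or_transporter: UGT2B7
    site: liver
    kinetics: {kcat: 174.386, enzyme_scale: 1.0, km: 10.0}
    product: licofelone-AGLU
  - kind: metabolism
    enzyme_or_transporter: CYP2J2
    site: liver
    kinetics: {kcat: 93.0055, enzyme_scale: 1.0, km: 10.0}
    product: OH-licofelone
  - kind: transport_influx
    enzyme_or_transporter: OATP1B1
    site: liver
    kinetics: {rate: 0.566113}
  - kind: clearance_biliary
    site: liver
    kinetics: {rate: 0.00232514}
metabolites:
  - name: licofelone-AGLU
    molecular_weight: 556.0
    fraction_unbound_plasma: 0.10
    partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.2}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.20}
  - name: OH-licofelone
    molecular_weight: 395.88
    fraction_unbound_plasma: 0.05
    partition_coefficients: {liver: 1.5, kidney: 2.0, periphery: 0.3}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
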
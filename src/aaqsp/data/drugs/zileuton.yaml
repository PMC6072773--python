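# Zileuton.  Dominant glucuronidation (UGT1A1); minor sulfoxidation by
# CYP3A4 (hence the negligible rifampicin interaction) and hydroxylation by
# CYP1A2; residual hepatic clearance lumps remaining pathways.
name: zileuton
molecular_weight: 236.29
fraction_unbound_plasma: 0.07
partition_coefficients:
  gut_wall: 1.5
  liver: 2.0
  kidney: 1.5
  periphery: 1.489
  blood_cells: 1.0
absorption: {ka: 0.00895105, lag: 1.00544, formulation: dissolved}
processes:
  - kind: metabolism
    enzyme_or_transporter: UGT1A1
    site: liver
    kinetics: {kcat: 98.3928, enzyme_scale: 1.0, km: 10.0}
    product: zileuton-GLU
  - kind: metabolism
    enzyme_or_transporter: CYP3A4
    site: liver
    kinetics: {kcat: 9.83928, enzyme_scale: 1.0, km: 10.0}
    product: zileuton-SO
  - kind: metabolism
    enzyme_or_transporter: CYP1A2
    site: liver
    kinetics: {kcat: 19.6786, enzyme_scale: 1.0, km: 10.0}
    product: OH-zileuton
  - kind: clearance_hepatic
    site: liver
    kinetics: {rate: 0.00655952}
metabolites:
  - name: zileuton-GLU
    molecular_weight: 412.42
    fraction_unbound_plasma: 0.20
    partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.3}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.20}
  - name: zileuton-SO
    molecular_weight: 252.29
    fraction_unbound_plasma: 0.15
    partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.4}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
  - name: OH-zileuton
    molecular_weight: 252.29
    fraction_unbound_plasma: 0.15
    partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.4}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
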
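# Diclofenac (free acid), dissolved oral formulation.
# ka, metabolism scale and peripheral Kp calibrated against the reduced
# model's target PK metrics at 25 mg oral (see scripts/fit_pbpk_params.py);
# pathway split: 4'-hydroxylation (CYP2C9, major), 3'-hydroxylation
# (CYP2C9), 5-hydroxylation (CYP3A4), acyl glucuronidation (UGT2B7).
name: diclofenac
molecular_weight: 296.15
fraction_unbound_plasma: 0.005
partition_coefficients:
  gut_wall: 1.5
  liver: 2.0
  kidney: 1.5
  periphery: 0.117752
  blood_cells: 1.0
absorption: {ka: 0.10205, lag: 5.00222, formulation: dissolved}
processes:
  - kind: metabolism
    enzyme_or_transporter: CYP2C9
    site: liver
    kinetics: {kcat: 806.291, enzyme_scale: 1.0, km: 10.0}
    product: 4'-OH-diclofenac
  - kind: metabolism
    enzyme_or_transporter: CYP2C9
    site: liver
    kinetics: {kcat: 181.416, enzyme_scale: 1.0, km: 10.0}
    product: 3'-OH-diclofenac
  - kind: metabolism
    enzyme_or_transporter: CYP3A4
    site: liver
    kinetics: {kcat: 262.045, enzyme_scale: 1.0, km: 10.0}
    product: 5-OH-diclofenac
  - kind: metabolism
    enzyme_or_transporter: UGT2B7
    site: liver
    kinetics: {kcat: 443.461, enzyme_scale: 1.0, km: 10.0}
    product: diclofenac-AGLU
metabolites:
  - name: 4'-OH-diclofenac
    molecular_weight: 312.15
    fraction_unbound_plasma: 0.05
    partition_coefficients: {liver: 1.5, kidney: 2.0, periphery: 0.3}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
  - name: 3'-OH-diclofenac
    molecular_weight: 312.15
    fraction_unbound_plasma: 0.05
    partition_coefficients: {liver: 1.5, kidney: 2.0, periphery: 0.3}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
  - name: 5-OH-diclofenac
    molecular_weight: 312.15
    fraction_unbound_plasma: 0.05
    partition_coefficients: {liver: 1.5, kidney: 2.0, periphery: 0.3}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.15}
  - name: diclofenac-AGLU
    molecular_weight: 472.29
    fraction_unbound_plasma: 0.10
    partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.2}
    processes:
      - kind: clearance_renal
        site: kidney
        kinetics: {rate: 0.20}
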
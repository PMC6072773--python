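# Celecoxib.  Hydroxylation mainly by CYP2C9 with a CYP3A4 contribution;
# hydroxy-celecoxib is oxidized to carboxy-celecoxib (alcohol dehydrogenase)
# which is renally cleared.  Slow absorption (Tmax ~2.8 h), large peripheral
# distribution (long half-life).
name: celecoxib
molecular_weight: 381.37
fraction_unbound_plasma: 0.03
partition_coefficients:
  gut_wall: 3.0
  liver: 4.0
  kidney: 3.0
  periphery: 3.74907
  blood_cells: 1.0
absorption: {ka: 0.00962025, lag: 40.0435, formulation: dissolved}
processes:
  - kind: metabolism
    enzyme_or_transporter: CYP2C9
    site: liver
    kinetics: {kcat: 163.029, enzyme_scale: 1.0, km: 10.0}
    product: OH-celecoxib
  - kind: metabolism
    enzyme_or_transporter: CYP3A4
    site: liver
    kinetics: {kcat: 39.127, enzyme_scale: 1.0, km: 10.0}
    product: OH-celecoxib
  - kind: clearance_biliary
    site: liver
    kinetics: {rate: 0.000978177}
  - kind: clearance_renal
    site: kidney
    kinetics: {rate: 0.000521693}
metabolites:
  - name: OH-celecoxib
    molecular_weight: 397.37
    fraction_unbound_plasma: 0.05
    partition_coefficients: {liver: 2.0, kidney: 2.0, periphery: 1.0}
    processes:
      - kind: metabolism
        enzyme_or_transporter: ADH
        site: liver
        kinetics: {kcat: 300.0, enzyme_scale: 1.0, km: 10.0}
        product: COOH-celecoxib
    metabolites:
      - name: COOH-celecoxib
        molecular_weight: 411.35
        fraction_unbound_plasma: 0.10
        partition_coefficients: {liver: 1.2, kidney: 2.0, periphery: 0.4}
        processes:
          - kind: clearance_renal
            site: kidney
            kinetics: {rate: 0.15}
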
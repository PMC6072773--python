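# Rifampicin (perpetrator drug).  Deacetylation by arylacetamide deacetylase
# (AADAC), OATP1B1 hepatic uptake, biliary and renal excretion.  The
# intracellular-liver unbound concentration drives PXR binding in the CYP
# induction cascade.
name: rifampicin
molecular_weight: 822.94
fraction_unbound_plasma: 0.17
partition_coefficients:
  gut_wall: 1.5
  liver: 3.0
  kidney: 1.5
  periphery: 0.654926
  blood_cells: 0.9
absorption: {ka: 0.0192529, lag: 27, formulation: dissolved}
processes:
  - kind: metabolism
    enzyme_or_transporter: AADAC
    site: liver
    kinetics: {kcat: 9.28326, enzyme_scale: 1.0, km: 10.0}
    product: desacetyl-rifampicin
  - kind: transport_influx
    enzyme_or_transporter: OATP1B1
    site: liver
    kinetics: {rate: 0.914747}
  - kind: clearance_biliary
    site: liver
    kinetics: {rate: 0.00618886}
  - kind: clearance_renal
    site: kidney
    kinetics: {rate: 0.0154721}
metabolites:
  - name: desacetyl-rifampicin
    molecular_weight: 780.9
    fraction_unbound_plasma: 0.20
    partition_coefficients: {liver: 2.0, kidney: 1.5, periphery: 0.5}
    processes:
      - kind: clearance_biliary
        site: liver
        kinetics: {rate: 0.01}
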
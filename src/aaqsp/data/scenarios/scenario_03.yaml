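id: 3
name: rifampicin pre-treatment + celecoxib
drugs: [{name: celecoxib, dose_mg: 100}]
rif_pretreatment: {dose_mg: 600, days: 7}
result_type: ddi_drug_efficacy
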
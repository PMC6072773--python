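id: 4
name: rifampicin pre-treatment + diclofenac
drugs: [{name: diclofenac, dose_mg: 50}]
rif_pretreatment: {dose_mg: 600, days: 7}
result_type: ddi_drug_efficacy
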
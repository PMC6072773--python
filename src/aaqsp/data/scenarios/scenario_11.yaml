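id: 11
name: rifampicin 600 mg x 5 d + celecoxib 200 mg (clinical DDI study)
drugs: [{name: celecoxib, dose_mg: 200}]
rif_pretreatment: {dose_mg: 600, days: 5}
result_type: ddi_validation
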
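id: 10
name: rifampicin 450 mg x 6 d + diclofenac 100 mg (clinical DDI study)
drugs: [{name: diclofenac, dose_mg: 100}]
rif_pretreatment: {dose_mg: 450, days: 6}
result_type: ddi_validation
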
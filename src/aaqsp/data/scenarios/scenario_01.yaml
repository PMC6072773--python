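id: 1
name: celecoxib single COX-2 inhibition
drugs: [{name: celecoxib, dose_mg: 100}]
result_type: drug_efficacy
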
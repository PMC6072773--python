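id: 6
name: celecoxib + zileuton co-treatment
drugs: [{name: celecoxib, dose_mg: 100}, {name: zileuton, dose_mg: 600}]
result_type: drug_efficacy
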
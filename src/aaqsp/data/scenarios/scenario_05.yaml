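id: 5
name: licofelone dual COX-2/5-LOX inhibition
drugs: [{name: licofelone, dose_mg: 200}]
result_type: drug_efficacy
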
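id: 8
name: diclofenac pain-relief correlation
drugs: [{name: diclofenac, dose_mg: 50}]
result_type: correlation
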
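id: 9
name: celecoxib pain-relief correlation
drugs: [{name: celecoxib, dose_mg: 400}]
result_type: correlation
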
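test_name,ref_low,ref_high
ALT,7,40
AST,10,40
platelets,150,400
bilirubin_total,0.2,1.2
albumin,3.5,5.0
INR,0.8,1.2
creatinine,0.6,1.3
hemoglobin,12,17
hba1c,4.0,5.6
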
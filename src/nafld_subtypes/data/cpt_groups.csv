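start,end,group
10021,19499,integumentary_surgery
20005,29999,musculoskeletal_surgery
30000,32999,respiratory_surgery
33010,37799,cardiovascular_surgery
40490,49999,digestive_surgery
50010,58999,urogenital_surgery
70010,76499,diagnostic_radiology
80047,89398,pathology_laboratory
90935,90999,dialysis
99201,99499,evaluation_management
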
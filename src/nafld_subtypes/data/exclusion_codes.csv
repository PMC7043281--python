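category,system,code
viral_hepatitis,ICD9,070.32
viral_hepatitis,ICD9,070.54
viral_hepatitis,ICD10,B18.1
viral_hepatitis,ICD10,B18.2
alcoholic_liver_disease,ICD9,571.0
alcoholic_liver_disease,ICD9,571.1
alcoholic_liver_disease,ICD9,571.2
alcoholic_liver_disease,ICD9,571.3
alcoholic_liver_disease,ICD10,K70.0
alcoholic_liver_disease,ICD10,K70.30
alcoholic_liver_disease,ICD10,K70.9
other_chronic_liver_disease,ICD9,571.6
other_chronic_liver_disease,ICD9,275.01
other_chronic_liver_disease,ICD9,275.1
other_chronic_liver_disease,ICD10,K74.3
other_chronic_liver_disease,ICD10,E83.110
other_chronic_liver_disease,ICD10,E83.01
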
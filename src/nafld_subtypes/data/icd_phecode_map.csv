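system,code,phecode,phenotype
ICD9,278.00,278.1,Obesity
ICD10,E66.9,278.1,Obesity
ICD9,250.00,250.2,Type 2 diabetes
ICD10,E11.9,250.2,Type 2 diabetes
ICD9,401.9,401.1,Essential hypertension
ICD10,I10,401.1,Essential hypertension
ICD9,272.4,272.1,Hyperlipidemia
ICD10,E78.5,272.1,Hyperlipidemia
ICD9,530.81,530.11,Gastroesophageal reflux disease
ICD10,K21.9,530.11,Gastroesophageal reflux disease
ICD9,493.90,495,Asthma
ICD10,J45.909,495,Asthma
ICD9,311,296.2,Depression
ICD10,F32.9,296.2,Depression
ICD9,300.00,300.1,Anxiety disorder
ICD10,F41.9,300.1,Anxiety disorder
ICD9,305.1,318,Tobacco use disorder
ICD10,F17.210,318,Tobacco use disorder
ICD9,327.23,327.3,Obstructive sleep apnea
ICD10,G47.33,327.3,Obstructive sleep apnea
ICD9,268.9,261.4,Vitamin D deficiency
ICD10,E55.9,261.4,Vitamin D deficiency
ICD9,427.31,427.21,Atrial fibrillation
ICD10,I48.91,427.21,Atrial fibrillation
ICD9,599.0,591,Urinary tract infection
ICD10,N39.0,591,Urinary tract infection
ICD9,486,480,Pneumonia
ICD10,J18.9,480,Pneumonia
ICD9,995.91,994.2,Sepsis
ICD10,A41.9,994.2,Sepsis
ICD9,199.1,195,Malignant neoplasm
ICD10,C80.1,195,Malignant neoplasm
ICD9,428.0,428.2,Heart failure
ICD10,I50.9,428.2,Heart failure
ICD9,496,496.21,Chronic obstructive pulmonary disease
ICD10,J44.9,496.21,Chronic obstructive pulmonary disease
ICD9,285.9,285,Anemia
ICD10,D64.9,285,Anemia
ICD9,244.9,244.4,Hypothyroidism
ICD10,E03.9,244.4,Hypothyroidism
ICD9,571.5,571.5,Chronic nonalcoholic liver disease
ICD9,571.8,571.5,Chronic nonalcoholic liver disease
ICD9,571.9,571.5,Chronic nonalcoholic liver disease
ICD10,K75.81,571.5,Chronic nonalcoholic liver disease
ICD10,K76.0,571.5,Chronic nonalcoholic liver disease
ICD10,K76.9,571.5,Chronic nonalcoholic liver disease
ICD9,155.0,155,Hepatocellular carcinoma
ICD9,155.2,155,Hepatocellular carcinoma
ICD10,C22.0,155,Hepatocellular carcinoma
ICD10,C22.8,155,Hepatocellular carcinoma
ICD9,585.9,585.3,Chronic kidney disease
ICD10,N18.9,585.3,Chronic kidney disease
ICD9,414.01,411.4,Ischemic heart disease
ICD10,I25.10,411.4,Ischemic heart disease
ICD9,410.90,411.2,Acute myocardial infarction
ICD10,I21.9,411.2,Acute myocardial infarction
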
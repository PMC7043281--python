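drug_name,ingredient
metformin,metformin
Glucophage,metformin
insulin glargine,insulin
insulin lispro,insulin
atorvastatin,atorvastatin
Lipitor,atorvastatin
omeprazole,omeprazole
Prilosec,omeprazole
aspirin,aspirin
lisinopril,lisinopril
amlodipine,amlodipine
metoprolol,metoprolol
furosemide,furosemide
Lasix,furosemide
oxycodone,oxycodone
acetaminophen,acetaminophen
Tylenol,acetaminophen
gabapentin,gabapentin
albuterol,albuterol
fluticasone,fluticasone
pantoprazole,pantoprazole
famotidine,famotidine
morphine,morphine
hydromorphone,hydromorphone
fentanyl,fentanyl
levothyroxine,levothyroxine
sertraline,sertraline
amiodarone,amiodarone
methotrexate,methotrexate
tamoxifen,tamoxifen
valproate,valproate
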
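key,display,target_table
2.16.840.1.113883.6.73,ATC,drug_exposure
ATC,ATC,drug_exposure
2.16.840.1.113883.6.1,LOINC,measurement
LOINC,LOINC,measurement
2.16.840.1.113883.6.3,ICD-10,condition_occurrence
ICD-10,ICD-10,condition_occurrence
ICD10,ICD-10,condition_occurrence
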
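rmim_class,target_table,rank,element_pattern,target_field
Patient,person,1,,
Patient,person,1,*hl7:administrativeGenderCode,gender_source_value
Patient,person,1,*hl7:birthTime,birth_datetime
Patient,person,1,*hl7:raceCode,race_source_value
Patient,person,1,*hl7:ethnicGroupCode,ethnicity_source_value
PatientRole,person,1,,
PatientRole,person,1,*hl7:administrativeGenderCode,gender_source_value
PatientRole,person,1,*hl7:birthTime,birth_datetime
PatientRole,person,1,*hl7:id,person_source_value
PatientRole,location,2,,
PatientRole,location,2,*hl7:addr/hl7:streetAddressLine,address_1
PatientRole,location,2,*hl7:addr/hl7:city,city
PatientRole,location,2,*hl7:addr/hl7:state,state
PatientRole,location,2,*hl7:addr/hl7:postalCode,zip
Encounter,visit_occurrence,1,,
Encounter,visit_occurrence,1,*hl7:effectiveTime/hl7:low,visit_start_date
Encounter,visit_occurrence,1,*hl7:effectiveTime/hl7:high,visit_end_date
Encounter,visit_occurrence,1,*hl7:code,visit_source_value
Observation,measurement,1,,
Observation,measurement,1,hl7:effectiveTime/hl7:low,measurement_date
Observation,measurement,1,hl7:effectiveTime,measurement_date
Observation,measurement,1,hl7:code,measurement_source_value
Observation,measurement,1,hl7:value,value_source_value
Observation,measurement,1,*hl7:interpretationCode,value_as_concept_id
Observation,observation,2,,
Observation,observation,2,hl7:effectiveTime/hl7:low,observation_date
Observation,observation,2,hl7:effectiveTime,observation_date
Observation,observation,2,hl7:code,observation_source_value
Observation,observation,2,hl7:value,value_source_value
ObservationMedia,observation,1,,
ObservationMedia,observation,1,hl7:value,value_source_value
Act,condition_occurrence,1,,
Act,condition_occurrence,1,*hl7:code,condition_source_value
Act,condition_occurrence,1,*hl7:effectiveTime/hl7:low,condition_start_date
Act,condition_occurrence,1,*hl7:effectiveTime/hl7:high,condition_end_date
Act,observation,2,,
Act,observation,2,*hl7:code,observation_source_value
Act,observation,2,*hl7:effectiveTime/hl7:low,observation_date
Procedure,procedure_occurrence,1,,
Procedure,procedure_occurrence,1,hl7:code,procedure_source_value
Procedure,procedure_occurrence,1,*hl7:effectiveTime/hl7:low,procedure_date
Procedure,procedure_occurrence,1,hl7:effectiveTime,procedure_date
SubstanceAdministration,drug_exposure,1,,
SubstanceAdministration,drug_exposure,1,*hl7:manufacturedMaterial/hl7:code,drug_source_value
SubstanceAdministration,drug_exposure,1,hl7:effectiveTime/hl7:low,drug_exposure_start_date
SubstanceAdministration,drug_exposure,1,hl7:effectiveTime/hl7:high,drug_exposure_end_date
SubstanceAdministration,drug_exposure,1,hl7:doseQuantity,quantity
SubstanceAdministration,drug_exposure,1,hl7:routeCode,route_source_value
Supply,drug_exposure,1,,
Supply,drug_exposure,1,*hl7:manufacturedMaterial/hl7:code,drug_source_value
Supply,drug_exposure,1,hl7:quantity,quantity
Supply,drug_exposure,1,hl7:effectiveTime/hl7:low,drug_exposure_start_date
Supply,drug_exposure,1,hl7:effectiveTime,drug_exposure_start_date
Specimen,specimen,1,,
Specimen,specimen,1,*hl7:code,specimen_source_value
Specimen,specimen,1,*hl7:effectiveTime,specimen_date
Specimen,specimen,1,*hl7:id,specimen_source_id
AssignedEntity,provider,1,,
AssignedEntity,provider,1,*hl7:assignedPerson/hl7:name,provider_name
AssignedEntity,provider,1,*hl7:code,specialty_source_value
AssignedEntity,provider,1,*hl7:id,provider_source_value
Person,provider,1,,
Person,provider,1,*hl7:name,provider_name
Organization,care_site,1,,
Organization,care_site,1,*hl7:name,care_site_name
Organization,care_site,1,*hl7:id,care_site_source_value
Organization,location,2,,
Organization,location,2,*hl7:addr/hl7:streetAddressLine,address_1
Organization,location,2,*hl7:addr/hl7:city,city
Organization,location,2,*hl7:addr/hl7:postalCode,zip
ClinicalDocument,observation_period,1,,
ClinicalDocument,observation_period,1,*hl7:effectiveTime/hl7:low,observation_period_start_date
ClinicalDocument,observation_period,1,*hl7:effectiveTime/hl7:high,observation_period_end_date
ClinicalDocument,visit_occurrence,2,,
ClinicalDocument,visit_occurrence,2,*hl7:effectiveTime/hl7:low,visit_start_date
ClinicalDocument,visit_occurrence,2,*hl7:effectiveTime/hl7:high,visit_end_date
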
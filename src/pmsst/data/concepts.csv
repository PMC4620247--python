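system,code,display
MedDRA,10051592,acute Coronary syndrome
MedDRA,10000891,Acute myocardial infarction
MedDRA,10002388,Unstable angina pectoris
MedDRA,10007559,Congestive heart failure
MedDRA,10067585,Type 2 diabetes mellitus
MedDRA,10020772,Hypertension
MedDRA,10019805,Hepatic failure
MedDRA,10038435,Renal failure
MedDRA,10003658,Atrial fibrillation
MedDRA,10008479,Cerebrovascular accident
MedDRA,10012601,Diabetes mellitus
MedDRA,10048858,Hypercholesterolaemia
MedDRA,10002383,Angina pectoris
MedDRA,10007541,Congestive cardiomyopathy
MedDRA,10061216,Chronic kidney disease
MedDRA,10006093,Bradycardia
MedDRA,10043071,Tachycardia
MedDRA,10037423,Pulmonary oedema
MedDRA,10027051,Myocardial ischaemia
MedDRA,10014698,Embolism
ICD9CM,410.0,Acute myocardial infarction of anterolateral wall
ICD9CM,411.1,Intermediate coronary syndrome (unstable angina)
ICD9CM,428.0,"Congestive heart failure, unspecified"
ICD9CM,250.00,Diabetes mellitus type 2 without complication
ICD9CM,401.9,Unspecified essential hypertension
ICD9CM,427.31,Atrial fibrillation
ICD9CM,434.91,Cerebral artery occlusion with infarction
ICD9CM,272.0,Pure hypercholesterolemia
ICD9CM,413.9,Other and unspecified angina pectoris
ICD9CM,425.4,Other primary cardiomyopathies
ICD9CM,585.9,"Chronic kidney disease, unspecified"
ICD9CM,427.89,Other specified cardiac dysrhythmias
ICD9CM,514,Pulmonary congestion and hypostasis
ICD9CM,411.89,Other acute and subacute forms of ischemic heart disease
ICD9CM,444.9,Embolism of unspecified artery
ICD9CM,584.9,"Acute kidney failure, unspecified"
ICD9CM,570,Acute and subacute necrosis of liver
ICD9CM,285.9,"Anemia, unspecified"
ICD9CM,486,"Pneumonia, organism unspecified"
ICD9CM,780.2,Syncope and collapse
LOCAL-OBS,SYSBP,Systolic blood pressure
LOCAL-OBS,DIABP,Diastolic blood pressure
LOCAL-OBS,WEIGHT,Body weight
LOCAL-OBS,HBA1C,Hemoglobin A1c
SEX,F,Female
SEX,M,Male
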
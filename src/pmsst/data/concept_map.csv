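system_a,code_a,system_b,code_b
MedDRA,10000891,ICD9CM,410.0
MedDRA,10002388,ICD9CM,411.1
MedDRA,10051592,ICD9CM,410.0
MedDRA,10051592,ICD9CM,411.1
MedDRA,10007559,ICD9CM,428.0
MedDRA,10067585,ICD9CM,250.00
MedDRA,10012601,ICD9CM,250.00
MedDRA,10020772,ICD9CM,401.9
MedDRA,10003658,ICD9CM,427.31
MedDRA,10008479,ICD9CM,434.91
MedDRA,10048858,ICD9CM,272.0
MedDRA,10002383,ICD9CM,413.9
MedDRA,10007541,ICD9CM,425.4
MedDRA,10061216,ICD9CM,585.9
MedDRA,10014698,ICD9CM,444.9
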
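phecode,icd,system,exclude_low,exclude_high
274.1,M10,ICD10,274,275.99
274.11,M10.0,ICD10,274,275.99
274.11,274.0,ICD9,274,275.99
401.1,I10,ICD10,401,405.99
401.1,4019,ICD9,401,405.99
411.2,I21,ICD10,410,414.99
411.2,410,ICD9,410,414.99
411.8,I25,ICD10,410,414.99
411.4,I25.0,ICD10,410,414.99
428.1,I50,ICD10,425,429.99
272.11,E78.0,ICD10,272,272.99
272.1,E78,ICD10,272,272.99
250.2,E11,ICD10,249,250.99
278.1,E66,ICD10,278,278.99
495,J45,ICD10,490,498.99
530.11,K21,ICD10,530,530.99
591,N39,ICD10,590,599.99
433.2,I63,ICD10,430,438.99
411.1,I20,ICD10,410,414.99
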
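service_name,code,points,unit_price,frequency_role,payer_group
Flat rate coverage per quarter,GOP 03000,157,16.99,per_quarter_gp,general_practitioner
Chronic illness surcharge on GOP 03000,GOP 03220,130,14.07,per_quarter_gp,general_practitioner
Surcharge on GOP 03220,GOP 03222,10,1.08,per_quarter_gp,general_practitioner
Detailed conversation,GOP 04230,90,9.74,per_quarter_gp,general_practitioner
Retainer fee (general practitioner),GOP 03040,144,15.58,per_quarter_gp,general_practitioner
Pneumological consultation (60 years and above),GOP 13642,210,22.73,per_quarter_pneumo,pneumologist
Surcharge (pneumologist) once per quarter,GOP 13644,41,4.44,per_quarter_pneumo,pneumologist
Bronchoscopy,GOP 13662,988,106.93,once,pneumologist
Bronchoalveolar lavage surcharge on GOP 13662,GOP 13663,242,26.19,once,pneumologist
ECG,EBM 27320,,0.00,zero_billable,methods
Audiometry,OPS 09320,147,15.91,per_audiometry,methods
Chest X-ray,EBM 34241,152,16.45,per_xray,methods
Ophthalmologic consultation,EBM 06212,150,16.23,per_ophtha_visit,methods
Computerized tomography,EBM 34330,660,71.43,per_ct,methods
Surcharge contrast agent,EBM 34345,228,24.68,per_ct,methods
Microscopy test for mycobacteria,EBM 32176,,5.20,per_sputum_sample,microbiology
Nucleic acid amplification test,EBM 32825,,61.40,once,microbiology
Culture test for mycobacteria (per material),EBM 32747,,34.90,per_sputum_sample,microbiology
Differentiation of mycobacteria,EBM 32764,,28.40,once,microbiology
Resistance definition,EBM 32770,,39.50,once,microbiology
Anti-HBc,EBM 32614,,5.90,once,laboratory
HBs-Ag,EBM 32781,,5.50,once,laboratory
Chloride,EBM 32084,,0.25,per_lab_visit,laboratory
Sodium,EBM 32083,,0.25,per_lab_visit,laboratory
Potassium,EBM 32081,,0.25,per_lab_visit,laboratory
Calcium,EBM 32082,,0.25,per_lab_visit,laboratory
Creatinine (Jaffe method),EBM 32066,,0.25,per_lab_visit,laboratory
Urea,EBM 32065,,0.25,per_lab_visit,laboratory
Blood count,EBM 32122,,1.10,per_lab_visit,laboratory
Bilirubin total,EBM 32058,,0.25,per_lab_visit,laboratory
Gamma-glutamyl transferase,EBM 32071,,0.25,per_lab_visit,laboratory
Glutamate-oxaloacetate transaminase,EBM 32069,,0.25,per_lab_visit,laboratory
Glutamate-pyruvate transaminase,EBM 32070,,0.25,per_lab_visit,laboratory
C-reactive protein,EBM 32460,,4.90,per_lab_visit,laboratory
Amikacin serum level,EBM 32341,,17.70,per_amk_level,laboratory
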
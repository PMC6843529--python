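name,abbreviation,pack_price,pack_quantity,daily_intake
Amikacin FRESENIUS 500 mg/100 mL,AMK,357.00,10,2
Clarithromycin-ratiopharm 500 mg,CLAM,19.52,20,2
Zithromax 250 mg,AZM,20.77,6,1
Clofazimin (LAMPREN) 100 mg,CLO,199.92,100,1
Ethambutol (EMB-Fatol) 400 mg,E,41.75,100,3
Moxifloxacin HEXAL 400 mg,MOX,39.73,10,1
Eremfat 600 mg,R,271.46,100,1
Rifabutin (MYCOBUTIN) 150 mg,RBT,489.19,90,2
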
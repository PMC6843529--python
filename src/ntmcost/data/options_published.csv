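regimen_label,category,duration_months,daily_drug_cost,drug_cost,monitoring_cost,total_cost
R-E-CLAM,macrolide_susceptible,14,5.91,2482.20,2162.47,4644.67
R-E-CLAM,macrolide_susceptible,18,5.91,3191.40,2895.75,6087.15
RBT-E-CLAM,macrolide_susceptible,14,14.08,5913.60,2162.47,8076.07
RBT-E-CLAM,macrolide_susceptible,18,14.08,7603.20,2895.75,10498.95
R-E-AZM,macrolide_susceptible,14,7.42,3116.40,2162.47,5287.87
R-E-AZM,macrolide_susceptible,18,7.42,4006.80,2895.75,6902.55
RBT-E-AZM,macrolide_susceptible,14,19.54,8206.80,2162.47,10369.27
RBT-E-AZM,macrolide_susceptible,18,19.54,10551.60,2895.75,13447.35
R-E-CLO-AMK,macrolide_resistant,14,5.96,6787.20,2263.30,9050.50
R-E-CLO-AMK,macrolide_resistant,18,5.96,7502.40,2996.58,10498.98
R-E-MOX-AMK,macrolide_resistant,14,7.93,7614.60,2263.30,9877.90
R-E-MOX-AMK,macrolide_resistant,18,7.93,8556.20,2996.58,11552.78
R-E-CLAM-AMX,severe,14,5.91,6766.20,2263.30,9029.50
R-E-CLAM-AMX,severe,18,5.91,7475.40,2996.58,10471.98
RBT-E-CLAM-AMX,severe,14,14.08,10197.60,2263.30,12460.90
RBT-E-CLAM-AMX,severe,18,14.08,11887.20,2996.58,14883.78
R-E-ATZ-AMX,severe,14,7.42,7400.40,2263.30,9663.70
R-E-ATZ-AMX,severe,18,7.42,8290.80,2996.58,11287.38
RBT-E-ATM-AMX,severe,14,19.54,12490.80,2263.30,14754.10
RBT-E-ATM-AMX,severe,18,19.54,12840.20,2996.58,15806.78
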
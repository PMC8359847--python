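label,drug,quantity,predicted_printed,observed,ratio_printed,units
simvastatin_60-91_oral,simvastatin,AUC,13.06,17.21,0.76,h*ug/L
simvastatin_60-91_oral,simvastatin,CL,16.24,19.80,0.82,L/h/kg
simvastatin_60-91_oral,simvastatin,Cmax,4.00,,,ug/L
midazolam_67-74_oral,midazolam,AUC,346.13,228.95,1.51,h*ug/L
midazolam_67-74_oral,midazolam,CL,1.00,1.11,0.90,L/h/kg
midazolam_67-74_oral,midazolam,Cmax,107.04,97.95,1.09,ug/L
midazolam_76-80_oral,midazolam,AUC,394.55,254.00,1.55,h*ug/L
midazolam_76-80_oral,midazolam,CL,0.89,0.93,0.95,L/h/kg
midazolam_76-80_oral,midazolam,Cmax,116.53,96.80,1.20,ug/L
theophylline_62-93_oral,theophylline,AUC,128.10,103.00,1.24,h*mg/L
theophylline_62-93_oral,theophylline,CL,24.58,36.50,0.67,mL/h/kg
theophylline_62-93_oral,theophylline,Cmax,19.87,16.12,1.23,mg/L
theophylline_60-70_iv,theophylline,AUC,154.67,167.80,0.92,h*mg/L
theophylline_60-70_iv,theophylline,CL,23.55,35.30,0.67,mL/h/kg
theophylline_60-70_iv,theophylline,Cmax,15.45,,,mg/L
ceftazidime_65-75_iv,ceftazidime,AUC,238.96,244.30,0.98,h*mg/L
ceftazidime_65-75_iv,ceftazidime,CL,62.81,58.24,1.08,mL/h/kg
ceftazidime_65-75_iv,ceftazidime,Cmax,85.69,101.40,0.85,mg/L
ceftazidime_68-73_iv,ceftazidime,AUC,227.76,234.25,0.97,h*mg/L
ceftazidime_68-73_iv,ceftazidime,CL,61.32,58.20,1.05,mL/h/kg
ceftazidime_68-73_iv,ceftazidime,Cmax,85.72,,,mg/L
ceftazidime_63-71_iv,ceftazidime,AUC,214.06,264.84,0.81,h*mg/L
ceftazidime_63-71_iv,ceftazidime,CL,65.84,60.61,1.09,mL/h/kg
ceftazidime_63-71_iv,ceftazidime,Cmax,84.95,101.36,0.84,mg/L
ceftazidime_60-73_iv,ceftazidime,AUC,239.50,,,h*mg/L
ceftazidime_60-73_iv,ceftazidime,CL,62.81,,,mL/h/kg
ceftazidime_60-73_iv,ceftazidime,Cmax,84.34,79.25,1.06,mg/L
gentamicin_62-73_iv,gentamicin,AUC,30.09,31.00,0.97,h*mg/L
gentamicin_62-73_iv,gentamicin,CL,56.47,41.56,1.36,mL/h/kg
gentamicin_62-73_iv,gentamicin,Cmax,7.70,11.52,0.67,mg/L
vancomycin_68-72_iv,vancomycin,AUC,276.31,280.30,0.99,h*mg/L
vancomycin_68-72_iv,vancomycin,CL,52.38,55.50,0.94,mL/h/kg
vancomycin_68-72_iv,vancomycin,Cmax,34.13,43.55,0.78,mg/L
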
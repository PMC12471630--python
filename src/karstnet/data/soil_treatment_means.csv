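# Soil physico-chemical properties (treatment mean and standard error, n = 5 blocks)
# from a 2x2x2 water (W) x nitrogen (N) x phosphorus (P) addition field experiment
# in a subtropical karst shrubland. Treatments: C control, W, N, P single additions,
# WN, WP, NP two-way, WNP three-way. Units: SWC %, SOC/TN/TP/TK g/kg, NH4/NO3/AP/AK
# mg/kg, Ca/Mg g/kg, pH and the C:N / C:P / N:P ratios unitless.
variable,C_mean,C_se,W_mean,W_se,N_mean,N_se,P_mean,P_se,WN_mean,WN_se,WP_mean,WP_se,NP_mean,NP_se,WNP_mean,WNP_se
SWC,46.6,2.5,53.3,1.3,47.0,1.0,50.9,3.2,50.4,3.1,51.5,0.9,49.1,1.4,53.2,1.4
pH,7.5,0.2,7.3,0.2,7.4,0.2,7.5,0.2,7.1,0.2,7.3,0.2,7.1,0.2,7.0,0.1
SOC,53.4,5.1,55.6,4.9,48.1,3.0,56.1,6.0,50.0,5.6,51.1,5.5,50.4,1.2,55.6,3.9
TN,4.9,0.3,5.1,0.7,6.2,1.8,5.6,0.5,4.7,0.5,4.5,0.4,3.8,0.4,4.4,0.4
TP,1.9,0.0,1.8,0.2,1.6,0.2,2.2,0.2,1.9,0.3,1.8,0.2,1.8,0.1,1.8,0.1
TK,4.0,0.6,4.4,0.5,4.4,0.4,4.0,0.4,4.6,0.4,4.6,0.5,4.3,0.4,5.0,0.5
C:N,11.0,1.1,11.2,0.7,9.1,1.2,10.0,0.7,10.6,0.6,11.5,0.5,14.0,1.6,13.1,1.3
C:P,28.8,2.8,31.8,1.3,30.1,1.2,27.4,4.2,27.5,2.4,29.2,1.9,28.9,1.1,31.5,1.1
N:P,2.6,0.1,2.9,0.1,3.6,0.6,2.7,0.3,2.6,0.2,2.6,0.3,2.2,0.3,2.5,0.2
NH4,11.5,1.2,11.5,1.2,9.6,0.6,11.5,0.9,11.0,0.7,11.1,1.2,9.6,0.6,12.1,1.0
NO3,16.3,1.9,16.6,1.6,25.8,2.3,20.3,6.1,32.6,6.4,14.8,1.1,23.8,1.8,25.0,4.3
AP,4.3,0.6,3.0,0.5,3.3,0.8,4.3,0.2,3.6,0.7,3.3,0.7,4.4,0.2,4.3,0.5
AK,108.4,3.0,108.6,4.5,98.9,4.7,112.4,6.0,103.1,4.6,108.8,6.8,97.2,3.7,107.8,6.1
Ca,3.1,0.3,2.9,0.3,2.7,0.2,3.3,0.3,2.7,0.2,2.6,0.3,2.7,0.2,2.7,0.2
Mg,3.3,0.0,3.0,0.2,3.0,0.2,3.6,0.2,2.8,0.3,2.8,0.3,3.0,0.2,2.9,0.3
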
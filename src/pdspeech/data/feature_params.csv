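feature,hc_mean,hc_sd,pd_mean,pd_sd
DDKavp,90.96,12.79,104.28,19.20
DDKsdp,35.07,25.70,57.54,38.66
DDKavr,5.63,0.62,4.99,0.77
DDKcvp,36.44,21.29,51.16,26.87
DDKjit,40.20,31.00,65.96,48.18
DDKsdi,3.56,1.07,4.05,1.21
DDKcvi,9.94,5.10,13.66,5.29
VOT,32.45,6.28,33.15,4.62
F2magn,1717.01,200.87,1679.77,208.23
F2rate,5.22,0.73,4.97,0.71
F2reg,20.70,13.27,36.74,27.83
F2aver,1559.27,185.04,1556.49,202.27
F2min,555.70,113.84,598.77,157.78
F2max,2730.40,361.71,2565.24,280.61
F0,175.62,42.14,160.22,47.09
F0std,2.80,1.35,11.09,13.36
vF0,1.63,0.78,7.19,8.95
Ampstd,3.83,1.46,4.18,1.03
vAmp,11.24,6.28,14.83,5.81
MPT,11.08,6.11,10.17,5.09
HNR,18.51,3.72,19.83,4.15
VowelArea,405882.13,222362.83,238256.90,148346.25
rF0,159.96,30.00,153.12,36.39
rSTD,35.20,12.03,30.17,11.80
rvF0,21.57,4.81,19.41,4.97
rvAm,32.19,3.40,30.40,4.33
TotalDur,32.45,5.83,38.19,9.52
NSR,5.13,1.01,4.12,0.92
DPI,200.56,78.11,256.90,96.40
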
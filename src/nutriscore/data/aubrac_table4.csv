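analyte,kind,male_mean,male_sd,female_mean,female_sd,significance,overall_mean,overall_sd
C10:0,acid,0.51,0.09,0.10,0.02,***,0.40,0.20
C12:0,acid,0.50,0.11,0.12,0.02,***,0.40,0.19
C14:0,acid,3.26,0.07,3.36,0.10,**,3.28,0.09
C14:1,acid,0.62,0.11,0.64,0.05,ns,0.63,0.09
C15:0,acid,0.47,0.05,0.50,0.06,ns,0.48,0.05
C16:0,acid,21.72,0.98,28.23,0.74,***,23.43,3.05
C16:1,acid,2.39,0.36,4.38,0.34,***,2.92,0.95
C17:0,acid,1.04,0.07,0.98,0.05,*,1.02,0.07
C18:0,acid,22.15,1.24,13.45,0.61,***,9.86,4.04
C18:1 cis,acid,34.02,1.10,39.31,0.54,***,35.41,2.56
C18:1 trans,acid,1.95,0.17,1.86,0.09,ns,1.93,0.16
C18:2 cis,acid,3.99,0.28,2.10,0.04,***,3.50,0.88
C18:3 cis n3,acid,0.44,0.03,0.56,0.09,***,0.47,0.07
C20:0,acid,0.08,0.14,0.09,0.01,ns,0.09,0.12
C20:1,acid,0.17,0.01,0.12,0.01,***,0.16,0.02
C18:2 trans,acid,2.52,0.28,0.14,0.01,***,1.89,1.09
n3,derived,0.44,0.03,0.56,0.09,***,0.47,0.07
n6,derived,6.51,0.45,2.23,0.05,***,5.39,1.95
tfa,derived,2.67,0.16,2.06,0.18,***,2.51,0.32
sfa,derived,49.73,1.90,46.82,0.38,***,48.96,2.08
mufa,derived,37.21,1.15,44.45,0.61,***,39.11,3.39
pufa,derived,4.43,0.29,2.66,0.10,***,3.96,0.83
ufa,derived,41.64,1.15,47.11,0.65,***,43.08,2.65
ufa_sfa_ratio,derived,0.84,0.04,1.01,0.02,***,0.88,0.08
n6_n3_ratio,derived,14.93,1.24,4.06,0.65,***,12.07,4.97
ai,index,0.798,,0.885,,***,0.821,0.05
ti,index,2.03,,1.74,,***,1.54,0.17
hfa,index,25.48,,31.71,,***,27.11,3.15
h_fa,index,6.38,,4.52,,***,5.89,0.93
h_over_H,index,0.250,,0.142,,***,0.217,0.06
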
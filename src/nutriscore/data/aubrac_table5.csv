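analyte,kind,male_mean,male_sd,female_mean,female_sd,significance,overall_mean,overall_sd
aspartic_acid,amino_acid,2.67,0.18,2.24,0.11,***,2.56,0.25
glutamic_acid,amino_acid,4.31,0.19,3.72,0.20,***,4.16,0.33
alanine,amino_acid,1.61,0.10,1.42,0.13,***,1.56,0.14
arginine,amino_acid,2.12,0.12,1.86,0.08,***,2.05,0.16
cystine_cysteine,amino_acid,0.29,0.02,0.27,0.02,*,0.28,0.02
phenylalanine,amino_acid,1.12,0.09,0.93,0.09,***,1.07,0.12
glycine,amino_acid,1.19,0.11,1.00,0.07,***,1.14,0.13
hydroxyproline,amino_acid,0.01,0.00,0.01,0.00,ns,0.01,0.00
isoleucine,amino_acid,1.33,0.11,1.12,0.12,***,1.28,0.14
histidine,amino_acid,1.17,0.10,0.95,0.09,***,1.11,0.13
leucine,amino_acid,2.35,0.14,1.89,0.11,***,2.23,0.25
lysine,amino_acid,2.60,0.16,2.15,0.15,***,2.48,0.26
methionine,amino_acid,0.75,0.06,0.60,0.06,***,0.71,0.08
proline,amino_acid,1.10,0.10,0.87,0.07,***,1.04,0.14
serine,amino_acid,1.21,0.11,1.02,0.07,***,1.16,0.13
tyrosine,amino_acid,1.04,0.10,0.88,0.06,***,1.00,0.12
threonine,amino_acid,1.30,0.08,1.09,0.11,***,1.25,0.13
tryptophan,amino_acid,3.06,0.25,2.85,0.27,*,3.00,0.27
valine,amino_acid,1.38,0.10,1.11,0.09,***,1.31,0.16
total_aa,derived,30.59,0.49,25.97,0.64,***,29.37,2.13
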
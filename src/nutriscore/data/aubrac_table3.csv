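analyte,male_mean,male_sd,female_mean,female_sd
water,75.00,0.43,71.84,0.19
dry_matter,25.00,0.43,28.16,0.19
protein,21.85,0.20,21.38,0.41
fat,1.88,0.06,4.80,0.10
minerals,1.05,0.06,0.82,0.06
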
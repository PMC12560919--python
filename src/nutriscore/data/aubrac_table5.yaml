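name: aubrac_table5
n_male: 27
n_female: 22
closure_total: null
models:
- {analyte: "aspartic_acid", group: male, mean: 2.67, sd: 0.18}
- {analyte: "aspartic_acid", group: female, mean: 2.24, sd: 0.11}
- {analyte: "glutamic_acid", group: male, mean: 4.31, sd: 0.19}
- {analyte: "glutamic_acid", group: female, mean: 3.72, sd: 0.2}
- {analyte: "alanine", group: male, mean: 1.61, sd: 0.1}
- {analyte: "alanine", group: female, mean: 1.42, sd: 0.13}
- {analyte: "arginine", group: male, mean: 2.12, sd: 0.12}
- {analyte: "arginine", group: female, mean: 1.86, sd: 0.08}
- {analyte: "cystine_cysteine", group: male, mean: 0.29, sd: 0.02}
- {analyte: "cystine_cysteine", group: female, mean: 0.27, sd: 0.02}
- {analyte: "phenylalanine", group: male, mean: 1.12, sd: 0.09}
- {analyte: "phenylalanine", group: female, mean: 0.93, sd: 0.09}
- {analyte: "glycine", group: male, mean: 1.19, sd: 0.11}
- {analyte: "glycine", group: female, mean: 1.0, sd: 0.07}
- {analyte: "hydroxyproline", group: male, mean: 0.01, sd: 0.0}
- {analyte: "hydroxyproline", group: female, mean: 0.01, sd: 0.0}
- {analyte: "isoleucine", group: male, mean: 1.33, sd: 0.11}
- {analyte: "isoleucine", group: female, mean: 1.12, sd: 0.12}
- {analyte: "histidine", group: male, mean: 1.17, sd: 0.1}
- {analyte: "histidine", group: female, mean: 0.95, sd: 0.09}
- {analyte: "leucine", group: male, mean: 2.35, sd: 0.14}
- {analyte: "leucine", group: female, mean: 1.89, sd: 0.11}
- {analyte: "lysine", group: male, mean: 2.6, sd: 0.16}
- {analyte: "lysine", group: female, mean: 2.15, sd: 0.15}
- {analyte: "methionine", group: male, mean: 0.75, sd: 0.06}
- {analyte: "methionine", group: female, mean: 0.6, sd: 0.06}
- {analyte: "proline", group: male, mean: 1.1, sd: 0.1}
- {analyte: "proline", group: female, mean: 0.87, sd: 0.07}
- {analyte: "serine", group: male, mean: 1.21, sd: 0.11}
- {analyte: "serine", group: female, mean: 1.02, sd: 0.07}
- {analyte: "tyrosine", group: male, mean: 1.04, sd: 0.1}
- {analyte: "tyrosine", group: female, mean: 0.88, sd: 0.06}
- {analyte: "threonine", group: male, mean: 1.3, sd: 0.08}
- {analyte: "threonine", group: female, mean: 1.09, sd: 0.11}
- {analyte: "tryptophan", group: male, mean: 3.06, sd: 0.25}
- {analyte: "tryptophan", group: female, mean: 2.85, sd: 0.27}
- {analyte: "valine", group: male, mean: 1.38, sd: 0.1}
- {analyte: "valine", group: female, mean: 1.11, sd: 0.09}
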
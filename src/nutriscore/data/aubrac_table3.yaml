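name: aubrac_table3
n_male: 27
n_female: 22
closure_total: null
models:
- {analyte: "water", group: male, mean: 75.0, sd: 0.43}
- {analyte: "water", group: female, mean: 71.84, sd: 0.19}
- {analyte: "dry_matter", group: male, mean: 25.0, sd: 0.43}
- {analyte: "dry_matter", group: female, mean: 28.16, sd: 0.19}
- {analyte: "protein", group: male, mean: 21.85, sd: 0.2}
- {analyte: "protein", group: female, mean: 21.38, sd: 0.41}
- {analyte: "fat", group: male, mean: 1.88, sd: 0.06}
- {analyte: "fat", group: female, mean: 4.8, sd: 0.1}
- {analyte: "minerals", group: male, mean: 1.05, sd: 0.06}
- {analyte: "minerals", group: female, mean: 0.82, sd: 0.06}
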
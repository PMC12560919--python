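name: aubrac_table4
n_male: 27
n_female: 22
closure_total: null
models:
- {analyte: "C10:0", group: male, mean: 0.51, sd: 0.09}
- {analyte: "C10:0", group: female, mean: 0.1, sd: 0.02}
- {analyte: "C12:0", group: male, mean: 0.5, sd: 0.11}
- {analyte: "C12:0", group: female, mean: 0.12, sd: 0.02}
- {analyte: "C14:0", group: male, mean: 3.26, sd: 0.07}
- {analyte: "C14:0", group: female, mean: 3.36, sd: 0.1}
- {analyte: "C14:1", group: male, mean: 0.62, sd: 0.11}
- {analyte: "C14:1", group: female, mean: 0.64, sd: 0.05}
- {analyte: "C15:0", group: male, mean: 0.47, sd: 0.05}
- {analyte: "C15:0", group: female, mean: 0.5, sd: 0.06}
- {analyte: "C16:0", group: male, mean: 21.72, sd: 0.98}
- {analyte: "C16:0", group: female, mean: 28.23, sd: 0.74}
- {analyte: "C16:1", group: male, mean: 2.39, sd: 0.36}
- {analyte: "C16:1", group: female, mean: 4.38, sd: 0.34}
- {analyte: "C17:0", group: male, mean: 1.04, sd: 0.07}
- {analyte: "C17:0", group: female, mean: 0.98, sd: 0.05}
- {analyte: "C18:0", group: male, mean: 22.15, sd: 1.24}
- {analyte: "C18:0", group: female, mean: 13.45, sd: 0.61}
- {analyte: "C18:1 cis", group: male, mean: 34.02, sd: 1.1}
- {analyte: "C18:1 cis", group: female, mean: 39.31, sd: 0.54}
- {analyte: "C18:1 trans", group: male, mean: 1.95, sd: 0.17}
- {analyte: "C18:1 trans", group: female, mean: 1.86, sd: 0.09}
- {analyte: "C18:2 cis", group: male, mean: 3.99, sd: 0.28}
- {analyte: "C18:2 cis", group: female, mean: 2.1, sd: 0.04}
- {analyte: "C18:3 cis n3", group: male, mean: 0.44, sd: 0.03}
- {analyte: "C18:3 cis n3", group: female, mean: 0.56, sd: 0.09}
- {analyte: "C20:0", group: male, mean: 0.08, sd: 0.14}
- {analyte: "C20:0", group: female, mean: 0.09, sd: 0.01}
- {analyte: "C20:1", group: male, mean: 0.17, sd: 0.01}
- {analyte: "C20:1", group: female, mean: 0.12, sd: 0.01}
- {analyte: "C18:2 trans", group: male, mean: 2.52, sd: 0.28}
- {analyte: "C18:2 trans", group: female, mean: 0.14, sd: 0.01}
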
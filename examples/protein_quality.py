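"""Protein quality of beef against FAO/WHO reference patterns.

Converts the packaged overall amino-acid profile (g/100 g meat) to
protein basis and scores it against the children / youth / adults
requirement patterns.
"""

from nutriscore import (
    evaluate_protein_quality,
    fixture_amino_acid_profile,
    fixture_protein_pct,
)

profile = fixture_amino_acid_profile("overall")
protein_pct = fixture_protein_pct("sex_mean")  # 21.615% protein

result = evaluate_protein_quality(profile, protein_pct)

print(f"Protein basis conversion at {protein_pct:.3f}% protein")
print(f"Total essential AA: {result.total_eaa:.2f} g/16 g N\n")
print(f"{'standard':<10}{'EAAI %':>9}{'BV %':>9}{'NI %':>8}  limiting AA")
for std in result.eaai:
    print(
        f"{std:<10}{result.eaai[std]:>9.2f}{result.bv[std]:>9.2f}"
        f"{result.ni[std]:>8.2f}  {result.limiting_aa[std]}"
    )

# EAAI > 100 means every essential amino-acid group exceeds the
# reference requirement; the limiting amino acid is the group with the
# lowest chemical score, i.e. the first to constrain utilization.
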
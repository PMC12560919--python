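"""Lipid health indices of a beef fatty-acid profile.

Builds the male-column FAME profile of the packaged Aubrac fixture and
computes the class sums and health indices under both dialects.
"""

from nutriscore import (
    fixture_fatty_acid_profile,
    lipid_quality,
    sum_fatty_acid_classes,
)

profile = fixture_fatty_acid_profile("male")

summary = sum_fatty_acid_classes(profile)
print("Class sums (% of total FAME):")
print(f"  SFA {summary.sfa:.2f}  MUFA {summary.mufa:.2f}  PUFA {summary.pufa:.2f}")
print(f"  UFA/SFA {summary.ufa_sfa_ratio:.3f}   n6/n3 {summary.n6_n3_ratio:.2f}")

for dialect in ("as_published", "conventional"):
    idx = lipid_quality(profile, dialect)
    print(f"\nIndices ({dialect}):")
    print(f"  AI  {idx.ai:.3f}   (athero-potential: lauric+palmitic+4*myristic vs unsaturates)")
    print(f"  TI  {idx.ti:.3f}   (thrombo-potential: weighted toward n-3 protection)")
    print(f"  h/H {idx.h_over_H:.3f} (hypo- vs hypercholesterolemic acids)")

# AI ~0.8 and TI ~2 are typical for beef; h/H under the as-published
# dialect uses trans-vaccenic as the C18:1 isomer, the conventional one
# uses oleic — hence the large h/H difference.
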
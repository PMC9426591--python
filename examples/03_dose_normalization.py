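"""Element-normalized dosing of candidate supplements.

Comparing supplements at equal molarity confounds their effect with their
carbon (or nitrogen) content, so screens normalize doses: each candidate is
dosed to deliver the same molar carbon as 50 mmol/gDW of glucose, or the
same molar nitrogen as 50 mmol/gDW of the 5-nitrogen target compound.
Doses are floored to integer mmol.
"""

from biostim import carbon_normalized_dose, nitrogen_normalized_dose
from biostim.datasets import named_supplements

print(f"{'supplement':<12} {'formula':<10} {'C dose':>7} {'N dose':>7}  (mmol/gDW)")
for spec in named_supplements():
    c_dose = carbon_normalized_dose(spec)
    try:
        n_dose = f"{nitrogen_normalized_dose(spec):.0f}"
    except ValueError:
        n_dose = "-"  # not a nitrogen source
    print(f"{spec.id:<12} {spec.formula:<10} {c_dose:>7.0f} {n_dose:>7}")

# A C12 disaccharide gets half the glucose dose (25), the C18 fatty acid
# floor(300/18) = 16, and single-nitrogen serine 250 to match the target's
# five nitrogens.
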
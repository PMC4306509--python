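"""Physicochemical transition matrices for motif-overlapping mutations.

Classifies two loss-of-charge substitutions of the kind seen in nuclear
localisation signals (arginine to alanine/serine) and prints the charge
transition matrix, its change fraction, and an exact test against a
same-size neutral-style set that preserves charge.
"""

import slimpact as sp

disease = [
    sp.MutationRecord("CERKL_SYN", 105, "R", "A", "inherited-disease"),
    sp.MutationRecord("CERKL_SYN", 106, "R", "S", "inherited-disease"),
]
neutral = [
    sp.MutationRecord("CERKL_SYN", 105, "R", "K", "neutral"),  # stays basic
    sp.MutationRecord("CERKL_SYN", 106, "R", "H", "neutral"),
]

for aa in ("R", "A", "S"):
    print(f"{aa}: charge={sp.subclass_of(aa, 'charge')}, "
          f"volume={sp.subclass_of(aa, 'volume')}")

m_disease = sp.transition_matrix(disease, "charge")
m_neutral = sp.transition_matrix(neutral, "charge")
print("charge transition counts (rows wt, cols mut):")
print(" labels:", m_disease.labels)
print(m_disease.counts)
print(f"change fraction disease: {sp.change_fraction(m_disease):.2f}, "
      f"neutral: {sp.change_fraction(m_neutral):.2f}")
print(f"exact p (change vs no-change): "
      f"{sp.property_change_test(m_disease, m_neutral):.3f}")
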
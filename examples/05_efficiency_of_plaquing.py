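"""Titres and efficiency of plaquing from dilution-series plate counts.

A host expressing an active homing endonuclease against the incoming phage
drops the EOP by orders of magnitude relative to the permissive control.
"""

from heg_atlas import PlaqueCount, eop_from_counts, titre_from_counts

control = [PlaqueCount("NZ9000/pPTPi", "sk1", -6, 100, 0.1)]
test = [PlaqueCount("NZ9000/pHNH7", "sk1", -4, 79, 0.1)]

print(f"control titre: {titre_from_counts(control):.3g} PFU/ml")
print(f"test titre:    {titre_from_counts(test):.3g} PFU/ml")

rec = eop_from_counts(test, control)
print(f"EOP = {rec.eop:.4f}  (fold reduction {rec.fold_reduction:.0f}x)")
# An EOP of 0.0079 means plaque formation dropped by two orders of
# magnitude: the endonuclease expressed by the test host is attacking the
# incoming phage genome.
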
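"""Classify the glycosidic conformation of purine nucleotides.

The base orientation about the glycosidic bond (chi, the O4'-C1'-N9-C4
torsion) distinguishes syn (chi in [-90, +90] deg) from anti nucleotides.
cGMP binds PKG I CNBD-A only in syn; cAMP can bind in either.
"""

from cnbdkit import build_purine_nucleotide, glycosidic_chi

for chi, base in [(45.0, "guanine"), (-150.0, "adenine"),
                  (90.0, "guanine"), (-90.0001, "adenine")]:
    lig = build_purine_nucleotide(chi, base=base)
    rec = glycosidic_chi(lig)
    print(f"{base:8s} chi = {rec.angle:+10.4f} deg -> {rec.classification}")

# +90.0000 is still syn (closed interval); -90.0001 is already anti.
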
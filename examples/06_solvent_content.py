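"""Matthews coefficient and solvent content of a crystal form.

Uses the hexagonal P6(2)22 cell of the CNBD-A co-crystals (a = b = 107 A,
c = 171 A) with two molecules per asymmetric unit and a residue-count MW
estimate for the 136-residue construct.
"""

from cnbdkit import CrystalInfo, approximate_protein_mw, matthews_solvent

crystal = CrystalInfo(a=107, b=107, c=171, alpha=90, beta=90, gamma=120,
                      space_group="P 62 2 2")
mw = approximate_protein_mw(136)
vol, vm, solvent = matthews_solvent(crystal, molecules_per_asu=2,
                                    molecular_weight=mw)
print(f"cell volume    = {vol:,.0f} A^3")
print(f"MW estimate    = {mw:,.0f} Da (136 residues x 110 Da + water)")
print(f"Matthews V_M   = {vm:.2f} A^3/Da")
print(f"solvent        = {solvent * 100:.1f} %")
# V_M near 4.7 A^3/Da is unusually high for protein crystals (typical
# 1.7-3.5): these crystals are about three-quarters solvent.
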
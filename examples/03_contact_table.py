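"""Build a protein-ligand contact table with hydrogen-bond/VDW classing.

Places a synthetic syn-guanine nucleotide next to a minimal probe pocket
(a Thr amide nitrogen, a Met carbon, a Cys thiol) and tabulates every
contact within 4.0 A.  N/O pairs within 3.5 A are hydrogen bonds; a
sulfur within 3.5 A of N/O is kept in the VDW class but flagged as an
extended hydrogen bond, matching how thiol-N7 contacts are reported for
cyclic-nucleotide pockets.
"""

import numpy as np

from cnbdkit import (Atom, Chain, Residue, StructureModel,
                     build_purine_nucleotide, find_contacts)

lig = build_purine_nucleotide(45.0, base="guanine")
n7 = lig.atom("N7").position
c8 = lig.atom("C8").position
normal = np.cross(c8 - n7, lig.atom("C5").position - n7)
normal /= np.linalg.norm(normal)     # unit normal of the purine plane
pocket = [
    Residue(name="THR", seq_number=193, atoms=[
        Atom(name="N", element="N", position=n7 + 2.8 * normal)]),
    Residue(name="MET", seq_number=175, atoms=[
        Atom(name="CE", element="C", position=c8 + 3.7 * normal)]),
    Residue(name="CYS", seq_number=173, atoms=[
        Atom(name="SG", element="S", position=n7 - 3.4 * normal)]),
]
model = StructureModel(chains=[Chain("A", pocket), Chain("L", [lig])])

print(f"{'residue':8s} {'atom':8s} {'ligand':6s} {'dist/A':>6s}  class (site)")
for r in find_contacts(model, lig):
    tag = " extended-Hbond" if r.extended else ""
    print(f"{r.residue:8s} {r.protein_atom:8s} {r.ligand_atom:6s} "
          f"{r.distance:6.2f}  {r.contact_class} ({r.site_label}){tag}")
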
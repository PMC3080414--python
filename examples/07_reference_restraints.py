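"""Select reference-model dihedral restraints by angular threshold.

In low-resolution refinement, torsions from a higher-resolution reference
structure are imposed on the working model only where the two models
already agree to within a threshold (15 deg by default), guiding topology
without forcing genuine conformational differences.  Here the working
model differs from the reference by a single 20-degree psi rotation, which
is correctly the only torsion excluded.
"""

from cnbdkit import build_polyalanine, select_reference_dihedrals
from cnbdkit.synth import place_atom

reference = build_polyalanine(8, phi=-57.0, psi=-47.0)
working = build_polyalanine(8, phi=-57.0, psi=-47.0)

# rotate psi(4) by +20 degrees by rebuilding residue 5 from new internal coords
ch = working.chains[0]
r4, r5 = ch.residue(4), ch.residue(5)
n4, ca4, c4 = (r4.atom(n).position for n in ("N", "CA", "C"))
n5 = place_atom(n4, ca4, c4, 1.329, 116.2, -47.0 + 20.0)
ca5 = place_atom(ca4, c4, n5, 1.458, 121.7, 180.0)
c5 = place_atom(c4, n5, ca5, 1.525, 111.0, -57.0)
r5.atom("N").position = n5
r5.atom("CA").position = ca5
r5.atom("C").position = c5
ch.residues = ch.residues[:5]
reference.chains[0].residues = reference.chains[0].residues[:5]

restraints = select_reference_dihedrals(working, reference, threshold=15.0)
for r in restraints:
    mark = "SELECTED" if r.selected else "EXCLUDED"
    print(f"{r.locus:10s} {r.torsion:4s} deviation {r.deviation:+7.2f} deg  {mark}")
print(f"\n{sum(r.selected for r in restraints)}/{len(restraints)} torsions restrained")
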
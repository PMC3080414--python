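"""Detect cis peptide bonds from the backbone omega torsion.

Builds two ideal dipeptides — one cis (omega = 0) and one trans
(omega = 180) — and scans them.  Non-proline cis peptides are rare and
structurally meaningful: in the cGMP pocket of PKG I CNBD-A the
Leu172–Cys173 cis link orients both side chains toward the purine ring.
"""

from cnbdkit import build_dipeptide, peptide_omega_scan

for omega in (0.0, 180.0, 29.9, 30.1):
    model = build_dipeptide(omega, residue_names=("LEU", "CYS"))
    link = peptide_omega_scan(model.chains[0])[0]
    print(f"omega = {link.omega:+8.2f} deg -> {link.classification:9s} "
          f"(cis window |omega| <= 30 deg; proline involved: {link.involves_proline})")

# The 29.9/30.1 pair brackets the cis window boundary: the classification
# flips from 'cis' to 'ambiguous' exactly at |omega| = 30 degrees.
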
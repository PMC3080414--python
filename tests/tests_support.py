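"""Shared independent oracles used by the property and acceptance tests.

These deliberately re-derive results along different mathematical routes
than the package (eigen-quaternion instead of SVD; exhaustive all-pairs
instead of the vectorized scan) so agreement is evidence, not tautology.
"""

import numpy as np

from cnbdkit import build_polyalanine, distance
from cnbdkit.synth import place_atom


def horn_rmsd(A, B):
    """Optimal-superposition RMSD via the closed-form quaternion
    eigenvalue method (independent of the SVD route)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    C = Bc.T @ Ac
    N = np.array([
        [C[0, 0] + C[1, 1] + C[2, 2], C[1, 2] - C[2, 1], C[2, 0] - C[0, 2], C[0, 1] - C[1, 0]],
        [C[1, 2] - C[2, 1], C[0, 0] - C[1, 1] - C[2, 2], C[0, 1] + C[1, 0], C[0, 2] + C[2, 0]],
        [C[2, 0] - C[0, 2], C[0, 1] + C[1, 0], -C[0, 0] + C[1, 1] - C[2, 2], C[1, 2] + C[2, 1]],
        [C[0, 1] - C[1, 0], C[0, 2] + C[2, 0], C[1, 2] + C[2, 1], -C[0, 0] - C[1, 1] + C[2, 2]],
    ])
    lam = np.linalg.eigvalsh(N)[-1]
    msd = (np.sum(Ac ** 2) + np.sum(Bc ** 2) - 2.0 * lam) / len(A)
    return np.sqrt(max(msd, 0.0))


def brute_force_contacts(model, ligand, hbond_cutoff=3.5, vdw_cutoff=4.0):
    """Exhaustive all-pairs contact set: {(protein atom, ligand atom,
    rounded distance, class)}."""
    out = set()
    lig_atoms = ligand.preferred_atoms()
    for ch in model.chains:
        for res in ch.residues:
            if res.is_hetero or res is ligand:
                continue
            for pa in res.preferred_atoms():
                for la in lig_atoms:
                    d = distance(pa.position, la.position)
                    if d <= vdw_cutoff:
                        cls = ("hydrogen_bond"
                               if d <= hbond_cutoff and pa.element in "NO"
                               and la.element in "NO" else "vdw")
                        out.add((pa.key, la.key, round(d, 9), cls))
    return out


def make_psi_perturbed_pair(delta_psi=20.0):
    """(working, reference) six-residue chains identical except for a
    *delta_psi*-degree change of psi at residue 5."""
    ref = build_polyalanine(10, phi=-57.0, psi=-47.0)
    work = build_polyalanine(10, phi=-57.0, psi=-47.0)
    ch = work.chains[0]
    r5, r6 = ch.residue(5), ch.residue(6)
    n5, ca5, c5 = (r5.atom(n).position for n in ("N", "CA", "C"))
    new_n6 = place_atom(n5, ca5, c5, 1.329, 116.2, -47.0 + delta_psi)
    r6.atom("N").position = new_n6
    ca6 = place_atom(ca5, c5, new_n6, 1.458, 121.7, 180.0)
    c6 = place_atom(c5, new_n6, ca6, 1.525, 111.0, -57.0)
    o6 = place_atom(new_n6, ca6, c6, 1.231, 120.5, -47.0 + 180.0)
    r6.atom("CA").position = ca6
    r6.atom("C").position = c6
    r6.atom("O").position = o6
    ch.residues = ch.residues[:6]
    ref.chains[0].residues = ref.chains[0].residues[:6]
    return work, ref
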
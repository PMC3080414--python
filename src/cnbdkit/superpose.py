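"""Least-squares superposition and reference-dihedral restraint selection.

The engine is the closed-form Kabsch solution (SVD with determinant
correction), wrapped in an iterative outlier-rejection loop that mimics
how structure-comparison tools report "equivalent N Calpha atoms": fit,
drop pairs deviating more than a cutoff, refit, until stable.

Restraint selection implements the reference-model rule used in
low-resolution crystallographic refinement: a torsion of the working model
is restrained to the reference value only when the circular deviation
between the two models is within a threshold (15 deg by default), so the
reference guides topology without forcing genuine differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import dihedral, wrap_angle
from .model import Chain, Residue, StructureModel

logger = logging.getLogger(__name__)

REJECT_CUTOFF = 2.0
MAX_CYCLES = 5
RESTRAINT_THRESHOLD = 15.0

#: side-chain chi torsion atom quadruples, chi1..chi4, per residue type
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

#: chi torsions whose terminal group is 2-fold symmetric (flip-degenerate)
SYMMETRIC_CHI = {("ASP", 2), ("GLU", 3), ("PHE", 2), ("TYR", 2)}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


class PairingError(ValueError):
    """No residue pairs could be formed between the two chains."""


class RejectionCollapseError(RuntimeError):
    """Outlier rejection removed every pair."""


@dataclass
class ResiduePairing:
    pairs: list[tuple[int, int]]     # (seq_number in A, seq_number in B)
    mode: str


@dataclass
class SuperpositionResult:
    rotation: np.ndarray             # (3, 3), proper
    translation: np.ndarray          # (3,)
    rmsd: float
    n_matched: int
    cycles_run: int = 0
    rejected: list[tuple[int, int]] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid motion to an (n, 3) coordinate array."""
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DihedralRestraint:
    locus: str                       # "A/THR193 psi" style
    torsion: str                     # phi | psi | chi1..chi4
    reference_angle: float
    deviation: float
    selected: bool


def pair_residues(chainA: Chain, chainB: Chain, mode: str = "by_number") -> ResiduePairing:
    """Pair residues of two chains, keeping only pairs with Calpha in both.

    ``by_number`` intersects author seq numbers; ``by_alignment`` pairs
    via a global sequence alignment (identical sequences reduce to the
    numbering intersection).
    """
    if len(chainA) == 0 or len(chainB) == 0:
        raise PairingError("empty chain")

    def ca_map(chain: Chain) -> dict[int, Residue]:
        return {r.seq_number: r for r in chain.polymer_residues() if r.atom("CA") is not None}

    mapA, mapB = ca_map(chainA), ca_map(chainB)
    if mode == "by_number":
        pairs = [(s, s) for s in sorted(set(mapA) & set(mapB))]
    elif mode == "by_alignment":
        from Bio import Align

        resA = [mapA[s] for s in sorted(mapA)]
        resB = [mapB[s] for s in sorted(mapB)]
        seqA = "".join(THREE_TO_ONE.get(r.name, "X") for r in resA)
        seqB = "".join(THREE_TO_ONE.get(r.name, "X") for r in resB)
        aligner = Align.PairwiseAligner(
            mode="global", match_score=2, mismatch_score=-1,
            open_gap_score=-5, extend_gap_score=-0.5,
        )
        aln = aligner.align(seqA, seqB)[0]
        pairs = []
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for k in range(a1 - a0):
                pairs.append((resA[a0 + k].seq_number, resB[b0 + k].seq_number))
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    if not pairs:
        raise PairingError(
            f"no Calpha-bearing residue pairs between chains "
            f"{chainA.chain_id!r} and {chainB.chain_id!r}"
        )
    return ResiduePairing(pairs=pairs, mode=mode)


def kabsch_fit(coordsA: Sequence, coordsB: Sequence) -> SuperpositionResult:
    """Optimal rigid superposition of B onto A (single pass).

    Returns rotation R and translation t with x' = R x + t minimizing the
    RMSD of the transformed B against A, via SVD of the covariance with
    the determinant sign correction that excludes reflections.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be equal-length (n, 3) arrays")
    if len(A) < 3:
        raise ValueError("need at least 3 point pairs for a rigid fit")
    cenA = A.mean(axis=0)
    cenB = B.mean(axis=0)
    H = (B - cenB).T @ (A - cenA)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cenA - R @ cenB
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_matched=len(A))


def align_with_rejection(
    chainA: Chain,
    chainB: Chain,
    pairing_mode: str = "by_number",
    max_cycles: int = MAX_CYCLES,
    reject_cutoff: float = REJECT_CUTOFF,
) -> SuperpositionResult:
    """Kabsch fit with iterative rejection of deviating Calpha pairs.

    Each cycle refits on the surviving pairs and drops every pair whose
    post-fit deviation exceeds *reject_cutoff*; stops when stable or after
    *max_cycles*.  The final ``n_matched`` is the "equivalent Calpha"
    count structure papers quote.
    """
    pairing = pair_residues(chainA, chainB, pairing_mode)
    resA = {r.seq_number: r for r in chainA.polymer_residues()}
    resB = {r.seq_number: r for r in chainB.polymer_residues()}
    current = list(pairing.pairs)
    rejected: list[tuple[int, int]] = []
    result: Optional[SuperpositionResult] = None
    cycles = 0
    for _ in range(max(1, max_cycles)):
        if len(current) < 3:
            raise RejectionCollapseError("outlier rejection left fewer than 3 pairs")
        A = np.array([resA[i].atom("CA").position for i, _ in current])
        B = np.array([resB[j].atom("CA").position for _, j in current])
        result = kabsch_fit(A, B)
        dev = np.linalg.norm(result.transform(B) - A, axis=1)
        bad = np.flatnonzero(dev > reject_cutoff)
        if len(bad) == 0:
            break
        cycles += 1
        if len(bad) == len(current):
            raise RejectionCollapseError("outlier rejection removed every pair")
        rejected.extend(current[k] for k in bad)
        current = [p for k, p in enumerate(current) if k not in set(bad)]
    assert result is not None
    result.cycles_run = cycles
    result.rejected = rejected
    result.n_matched = len(current)
    return result


def _backbone_torsions(chain: Chain) -> dict[tuple[int, str], float]:
    out: dict[tuple[int, str], float] = {}
    residues = chain.polymer_residues()
    for k, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        if None in (n, ca, c):
            continue
        if k > 0:
            prev_c = residues[k - 1].atom("C")
            if prev_c is not None:
                out[(res.seq_number, "phi")] = dihedral(
                    prev_c.position, n.position, ca.position, c.position)
        if k + 1 < len(residues):
            next_n = residues[k + 1].atom("N")
            if next_n is not None:
                out[(res.seq_number, "psi")] = dihedral(
                    n.position, ca.position, c.position, next_n.position)
        for ci, quad in enumerate(CHI_ATOMS.get(res.name, []), start=1):
            atoms = [res.atom(a) for a in quad]
            if any(a is None for a in atoms):
                continue
            out[(res.seq_number, f"chi{ci}")] = dihedral(*(a.position for a in atoms))
    return out


def _chain_resnames(chain: Chain) -> dict[int, str]:
    return {r.seq_number: r.name for r in chain.polymer_residues()}


def select_reference_dihedrals(
    working: StructureModel,
    reference: StructureModel,
    threshold: float = RESTRAINT_THRESHOLD,
) -> list[DihedralRestraint]:
    """Reference-model restraint selection by circular angular deviation.

    Every backbone (phi, psi) and side-chain chi torsion computable in
    both models is compared; a torsion is selected for restraint iff the
    wrapped deviation |working - reference| is within *threshold* degrees.
    Chi torsions with 2-fold-symmetric termini are compared modulo 180 deg
    so chemically equivalent flips do not defeat selection.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    restraints: list[DihedralRestraint] = []
    for chW in working.chains:
        chR = reference.chain(chW.chain_id) or (
            reference.chains[0] if len(reference.chains) == 1 else None)
        if chR is None:
            continue
        torsW = _backbone_torsions(chW)
        torsR = _backbone_torsions(chR)
        namesW = _chain_resnames(chW)
        for key in sorted(set(torsW) & set(torsR)):
            seq, tname = key
            dev = wrap_angle(torsW[key] - torsR[key])
            resname = namesW.get(seq, "UNK")
            if tname.startswith("chi") and (resname, int(tname[3:])) in SYMMETRIC_CHI:
                dev = wrap_angle(dev)
                if dev > 90.0:
                    dev -= 180.0
                elif dev <= -90.0:
                    dev += 180.0
            restraints.append(
                DihedralRestraint(
                    locus=f"{chW.chain_id}/{resname}{seq}",
                    torsion=tname,
                    reference_angle=torsR[key],
                    deviation=dev,
                    selected=abs(dev) <= threshold,
                )
            )
    if not restraints:
        raise ValueError("no torsion is computable in both models")
    return restraints
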
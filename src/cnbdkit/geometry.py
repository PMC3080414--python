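"""Metric and torsion geometry on coordinate models.

Distances, signed dihedrals, cis/trans peptide (omega) classification,
glycosidic syn/anti classification of purine nucleotides, protein–ligand
contact tables with hydrogen-bond/van-der-Waals classing and binding-site
annotation, disulfide-candidate search, and per-residue Calpha B-factor
profiles.

Conventions
-----------
* omega(i, i+1) is the CA(i)–C(i)–N(i+1)–CA(i+1) torsion; cis means
  |omega| <= 30 deg, trans |omega - 180| <= 30 deg (wrapped), anything
  else is flagged ambiguous.
* The purine glycosidic torsion chi is O4'–C1'–N9–C4; syn is the closed
  interval [-90, +90] deg, anti is everything else.
* A hydrogen bond is a heavy-atom pair, both N or O, within 3.5 A.  Pairs
  where one atom is sulfur within the same cutoff keep van-der-Waals class
  but carry ``extended=True`` (the "extended hydrogen bond" of Cys
  thiol-to-N7 contacts); no angular term is used because the models carry
  no hydrogens.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Atom, Chain, Residue, StructureModel, normalize_atom_name

logger = logging.getLogger(__name__)

CIS_WINDOW = 30.0
SYN_WINDOW = 90.0
HBOND_CUTOFF = 3.5
VDW_CUTOFF = 4.0
DISULFIDE_CUTOFF = 4.5
HBOND_ELEMENTS = frozenset({"N", "O"})

#: binding-site decomposition of the cyclic-nucleotide pocket:
#: site 1 — P-helix backbone amides plus the conserved arginine that grip
#: the cyclic phosphate; site 2 — the threonine bridging phosphate and
#: base; site 3 — the cis-peptide pair docking the purine ring.
DEFAULT_SITE_MAP = {
    "site1": frozenset({182, 183, 184, 185, 192}),
    "site2": frozenset({193}),
    "site3": frozenset({172, 173}),
    "near_site3": frozenset({165, 175}),
}


def distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points, in Angstrom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees to (-180, +180]."""
    out = math.fmod(angle, 360.0)
    if out <= -180.0:
        out += 360.0
    elif out > 180.0:
        out -= 360.0
    return out


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, range (-180, +180].

    Standard atan2 construction on the two bond-plane normals; invariant
    under rigid transforms, negated by mirror reflection.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-9:
        raise ValueError("degenerate dihedral: central atoms coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("degenerate dihedral: colinear bounding triple")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / nb2)
    ang = math.degrees(math.atan2(y, x))
    return wrap_angle(ang)


def classify_omega(omega: float, cis_window: float = CIS_WINDOW) -> str:
    if abs(wrap_angle(omega)) <= cis_window:
        return "cis"
    if abs(wrap_angle(omega - 180.0)) <= cis_window:
        return "trans"
    return "ambiguous"


@dataclass
class TorsionRecord:
    kind: str                      # "omega" | "chi_glycosidic"
    locus: str
    angle: float
    classification: str


@dataclass
class PeptideLink:
    residue_i: str
    residue_iplus1: str
    seq_i: int
    seq_iplus1: int
    omega: float
    is_cis: bool
    involves_proline: bool
    classification: str


@dataclass
class ContactRecord:
    chain_id: str
    residue: str                   # e.g. "THR193"
    seq_number: int
    protein_atom: str
    ligand_atom: str
    distance: float
    contact_class: str             # "hydrogen_bond" | "vdw"
    extended: bool = False         # S-mediated contact within H-bond range
    site_label: str = "none"


@dataclass
class BFactorProfile:
    chain_id: str
    entries: list[tuple[int, float]]
    region_means: dict[str, Optional[float]] = field(default_factory=dict)

    @property
    def chain_mean(self) -> float:
        return float(np.mean([b for _, b in self.entries]))


def peptide_omega_scan(chain: Chain, cis_window: float = CIS_WINDOW) -> list[PeptideLink]:
    """Omega torsion of every consecutive residue pair with complete backbone.

    Pairs missing any of CA(i), C(i), N(i+1), CA(i+1) are skipped with a
    log message rather than raising.
    """
    residues = chain.polymer_residues()
    links: list[PeptideLink] = []
    for ri, rj in zip(residues, residues[1:]):
        atoms = (ri.atom("CA"), ri.atom("C"), rj.atom("N"), rj.atom("CA"))
        if any(a is None for a in atoms):
            logger.debug("omega scan: incomplete backbone at %s-%s", ri.id, rj.id)
            continue
        omega = dihedral(*(a.position for a in atoms))
        cls = classify_omega(omega, cis_window)
        links.append(
            PeptideLink(
                residue_i=ri.id, residue_iplus1=rj.id,
                seq_i=ri.seq_number, seq_iplus1=rj.seq_number,
                omega=omega, is_cis=(cls == "cis"),
                involves_proline=("PRO" in (ri.name, rj.name)),
                classification=cls,
            )
        )
    return links


def glycosidic_chi(ligand: Residue, syn_window: float = SYN_WINDOW) -> TorsionRecord:
    """Purine glycosidic torsion chi (O4'-C1'-N9-C4) with syn/anti call.

    syn is the closed interval [-syn_window, +syn_window].
    """
    quad = []
    for name in ("O4'", "C1'", "N9", "C4"):
        atom = ligand.atom(name)
        if atom is None:
            raise KeyError(f"ligand {ligand.id} lacks atom {name} for the glycosidic torsion")
        quad.append(atom.position)
    chi = dihedral(*quad)
    cls = "syn" if -syn_window <= chi <= syn_window else "anti"
    return TorsionRecord(kind="chi_glycosidic", locus=ligand.id, angle=chi, classification=cls)


def _site_of(seq_number: int, site_map: dict) -> str:
    for label, numbers in site_map.items():
        if seq_number in numbers:
            return label
    return "none"


def find_contacts(
    model: StructureModel,
    ligand: Residue,
    hbond_cutoff: float = HBOND_CUTOFF,
    vdw_cutoff: float = VDW_CUTOFF,
    site_map: Optional[dict] = None,
    protein_chains: Optional[Iterable[str]] = None,
) -> list[ContactRecord]:
    """All protein-atom/ligand-atom pairs within *vdw_cutoff*.

    Pairs within *hbond_cutoff* whose atoms are both N/O are classed
    hydrogen bonds; everything else is van-der-Waals.  Sulfur-mediated
    pairs within *hbond_cutoff* are flagged ``extended``.  Records are
    ordered by protein residue, then distance.
    """
    if hbond_cutoff <= 0 or vdw_cutoff <= 0 or hbond_cutoff > vdw_cutoff:
        raise ValueError("cutoffs must be positive with hbond_cutoff <= vdw_cutoff")
    if site_map is None:
        site_map = DEFAULT_SITE_MAP
    if not any(ligand is r for c in model.chains for r in c.residues):
        raise LookupError(f"ligand {ligand.id} is not part of the model")
    wanted = set(protein_chains) if protein_chains is not None else None

    lig_atoms = [a for a in ligand.preferred_atoms() if a.element != "H"]
    lig_pos = np.array([a.position for a in lig_atoms])
    records: list[ContactRecord] = []
    for ch in model.chains:
        if wanted is not None and ch.chain_id not in wanted:
            continue
        for res in ch.residues:
            if res.is_hetero or res is ligand:
                continue
            for atom in res.preferred_atoms():
                if atom.element == "H":
                    continue
                d = np.linalg.norm(lig_pos - atom.position, axis=1)
                for j in np.flatnonzero(d <= vdw_cutoff):
                    dist = float(d[j])
                    la = lig_atoms[j]
                    in_hb_range = dist <= hbond_cutoff
                    both_no = atom.element in HBOND_ELEMENTS and la.element in HBOND_ELEMENTS
                    has_s = "S" in (atom.element, la.element)
                    other_no = (
                        atom.element in HBOND_ELEMENTS or la.element in HBOND_ELEMENTS
                    )
                    records.append(
                        ContactRecord(
                            chain_id=ch.chain_id,
                            residue=f"{res.name}{res.seq_number}",
                            seq_number=res.seq_number,
                            protein_atom=atom.key,
                            ligand_atom=la.key,
                            distance=dist,
                            contact_class="hydrogen_bond" if (in_hb_range and both_no) else "vdw",
                            extended=bool(in_hb_range and has_s and other_no),
                            site_label=_site_of(res.seq_number, site_map),
                        )
                    )
    records.sort(key=lambda r: (r.chain_id, r.seq_number, r.distance))
    return records


def collapse_leu_cd(records: list[ContactRecord]) -> list[ContactRecord]:
    """Report leucine CD1/CD2 contacts as a single minimum-distance row.

    Published contact tables sometimes label a leucine delta-carbon contact
    plainly "CD"; leucine has CD1 and CD2, so the collapsed row is keyed
    "CD(min)" and carries the shorter of the two distances per ligand atom.
    """
    out: list[ContactRecord] = []
    best: dict[tuple, ContactRecord] = {}
    for rec in records:
        if rec.residue.startswith("LEU") and rec.protein_atom in ("CD1", "CD2"):
            key = (rec.chain_id, rec.seq_number, rec.ligand_atom)
            if key not in best or rec.distance < best[key].distance:
                merged = ContactRecord(**{**rec.__dict__, "protein_atom": "CD(min)"})
                best[key] = merged
        else:
            out.append(rec)
    out.extend(best.values())
    out.sort(key=lambda r: (r.chain_id, r.seq_number, r.distance))
    return out


def count_hydrogen_bonds(records: Iterable[ContactRecord]) -> int:
    return sum(1 for r in records if r.contact_class == "hydrogen_bond")


def find_disulfide_candidates(
    model: StructureModel, cutoff: float = DISULFIDE_CUTOFF
) -> list[tuple[str, str, float]]:
    """Cysteine SG–SG pairs (distinct residues) within *cutoff* Angstrom.

    Covers pairs within and across chains.  The default cutoff (4.5 A) is
    deliberately wider than the 2.05 A bonded S–S distance: reduced thiols
    poised to form a disulfide on oxidation sit apart.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sgs: list[tuple[str, Atom]] = []
    for ch in model.chains:
        for res in ch.residues:
            if res.name == "CYS":
                sg = res.atom("SG")
                if sg is not None:
                    sgs.append((f"{ch.chain_id}/CYS{res.seq_number}", sg))
    out = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = distance(sgs[i][1].position, sgs[j][1].position)
            if d <= cutoff:
                out.append((sgs[i][0], sgs[j][0], d))
    return out


def bfactor_profile(
    chain: Chain, regions: Optional[dict[str, tuple[int, int]]] = None
) -> BFactorProfile:
    """Per-residue Calpha B-factors plus mean B over named residue spans.

    Spans are inclusive ``(first, last)`` author seq numbers; a span with
    no Calpha in the chain gets a ``None`` mean (flagged, not an error).
    """
    if len(chain.residues) == 0:
        raise ValueError("empty chain")
    entries: list[tuple[int, float]] = []
    for res in chain.polymer_residues():
        ca = res.atom("CA")
        if ca is None:
            logger.debug("bfactor profile: no CA in %s", res.id)
            continue
        entries.append((res.seq_number, ca.b_factor))
    means: dict[str, Optional[float]] = {}
    for label, (lo, hi) in (regions or {}).items():
        vals = [b for s, b in entries if lo <= s <= hi]
        means[label] = float(np.mean(vals)) if vals else None
        if not vals:
            logger.warning("region %s [%d, %d] has no Calpha atoms in chain %s",
                           label, lo, hi, chain.chain_id)
    return BFactorProfile(chain_id=chain.chain_id, entries=entries, region_means=means)
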
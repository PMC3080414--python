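"""Synthetic fixtures: ideal dipeptides, purine nucleotides, perturbed
chain copies and noisy titrations.

Structural fixtures are built from internal coordinates (bond length, bond
angle, torsion) by the NeRF construction, so a requested torsion is hit to
float precision.  The templates use standard small-molecule geometry; the
nucleotide ribose is an idealized open template — its ring closure is
approximate, which is irrelevant for glycosidic-torsion and contact tests
but means the fixture is not a chemically exact ribose.

Every stochastic fixture takes a mandatory seed and is reproducible
byte-for-byte from its spec.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.transform import Rotation

from .itc import OneSiteParams, TitrationCurve, TitrationDesign, simulate_titration
from .model import Atom, Chain, Residue, StructureModel


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position D given A, B, C with |CD| = bond, angle(B,C,D) and
    dihedral(A,B,C,D) in degrees (NeRF construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("colinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def _mk_atom(name: str, pos, serial: int, b: float = 20.0) -> Atom:
    return Atom(name=name, element=_element_of(name), position=np.asarray(pos, float),
                occupancy=1.0, b_factor=b, serial=serial)


# ---------------------------------------------------------------------------
# dipeptide

# ideal backbone internal coordinates (Engh–Huber-style values)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.5


def build_dipeptide(
    omega: float,
    residue_names: tuple[str, str] = ("ALA", "ALA"),
    psi1: float = 150.0,
    phi2: float = -120.0,
) -> StructureModel:
    """Two-residue peptide with the inter-residue omega torsion set exactly.

    omega is the CA1–C1–N2–CA2 torsion in degrees, (-180, 180].
    """
    if not -180.0 < omega <= 180.0:
        raise ValueError("omega must lie in (-180, 180]")
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c1 = ca1 + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    n2 = place_atom(n1, ca1, c1, _B_C_N, _A_CA_C_N, psi1)
    o1 = place_atom(n1, ca1, c1, _B_C_O, _A_CA_C_O, psi1 + 180.0)
    ca2 = place_atom(ca1, c1, n2, _B_N_CA, _A_C_N_CA, omega)
    c2 = place_atom(c1, n2, ca2, _B_CA_C, _A_N_CA_C, phi2)
    o2 = place_atom(n2, ca2, c2, _B_C_O, _A_CA_C_O, -45.0)

    def side_chain(n, ca, c):
        return place_atom(c, n, ca, 1.53, 110.5, -122.0)

    serial = 0
    residues = []
    for i, (rname, coords) in enumerate(
        [(residue_names[0], [("N", n1), ("CA", ca1), ("C", c1), ("O", o1)]),
         (residue_names[1], [("N", n2), ("CA", ca2), ("C", c2), ("O", o2)])],
        start=1,
    ):
        atoms = []
        for aname, pos in coords:
            serial += 1
            atoms.append(_mk_atom(aname, pos, serial))
        if rname != "GLY":
            serial += 1
            n_, ca_, c_ = (coords[0][1], coords[1][1], coords[2][1])
            atoms.append(_mk_atom("CB", side_chain(n_, ca_, c_), serial))
        residues.append(Residue(name=rname, seq_number=i, atoms=atoms))
    return StructureModel(chains=[Chain(chain_id="A", residues=residues)],
                          source_id=f"dipeptide_omega{omega:+.1f}")


def build_polyalanine(n_residues: int = 12, omega: float = 180.0,
                      phi: float = -57.0, psi: float = -47.0) -> StructureModel:
    """Poly-alanine chain with uniform (phi, psi, omega); helical defaults."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(180.0 - _A_N_CA_C)
    c = ca + _B_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    residues = []
    serial = 0
    for i in range(1, n_residues + 1):
        o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        atoms = []
        for aname, pos in [("N", n), ("CA", ca), ("C", c), ("O", o)]:
            serial += 1
            atoms.append(_mk_atom(aname, pos, serial))
        residues.append(Residue(name="ALA", seq_number=i, atoms=atoms))
        if i < n_residues:
            n_next = place_atom(n, ca, c, _B_C_N, _A_CA_C_N, psi)
            ca_next = place_atom(ca, c, n_next, _B_N_CA, _A_C_N_CA, omega)
            c_next = place_atom(c, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
    return StructureModel(chains=[Chain(chain_id="A", residues=residues)],
                          source_id=f"polyala{n_residues}")


# ---------------------------------------------------------------------------
# purine nucleotide

def build_purine_nucleotide(
    chi: float,
    base: str = "guanine",
    cyclic_phosphate: bool = True,
    seq_number: int = 1,
) -> Residue:
    """Purine nucleotide template with the glycosidic torsion set exactly.

    chi is the O4'–C1'–N9–C4 torsion in degrees, (-180, 180]; syn sits in
    [-90, 90].  Atom names use the primed dialect (O4', C1', ...).
    """
    if not -180.0 < chi <= 180.0:
        raise ValueError("chi must lie in (-180, 180]")
    if base not in ("guanine", "adenine"):
        raise ValueError("base must be 'guanine' or 'adenine'")
    c4p = np.array([0.0, 0.0, 0.0])
    o4p = np.array([1.45, 0.0, 0.0])
    a = math.radians(180.0 - 109.5)
    c1p = o4p + 1.41 * np.array([math.cos(a), math.sin(a), 0.0])
    n9 = place_atom(c4p, o4p, c1p, 1.47, 108.5, -120.0)
    c4 = place_atom(o4p, c1p, n9, 1.37, 126.0, chi)
    c8 = place_atom(o4p, c1p, n9, 1.37, 128.0, chi + 180.0)
    n7 = place_atom(c1p, n9, c8, 1.31, 113.5, 180.0)
    c5 = place_atom(c1p, n9, c4, 1.38, 106.0, 180.0)
    n3 = place_atom(c1p, n9, c4, 1.35, 126.0, 0.0)
    c2 = place_atom(c5, c4, n3, 1.33, 112.0, 0.0)
    n1 = place_atom(c4, n3, c2, 1.36, 119.0, 0.0)
    c6 = place_atom(n3, c2, n1, 1.41, 118.0, 0.0)

    pos = {
        "C4'": c4p, "O4'": o4p, "C1'": c1p, "N9": n9, "C4": c4, "C8": c8,
        "N7": n7, "C5": c5, "N3": n3, "C2": c2, "N1": n1, "C6": c6,
    }
    if base == "guanine":
        pos["O6"] = place_atom(c2, n1, c6, 1.23, 120.0, 180.0)
        pos["N2"] = place_atom(c4, n3, c2, 1.34, 120.0, 180.0)
    else:
        pos["N6"] = place_atom(c2, n1, c6, 1.34, 120.0, 180.0)

    # ribose completion (open template) and 3',5'-cyclic phosphate arm
    pos["C2'"] = place_atom(n9, o4p, c1p, 1.53, 106.0, -120.0)
    pos["O2'"] = place_atom(o4p, c1p, pos["C2'"], 1.41, 110.0, -120.0)
    pos["C3'"] = place_atom(o4p, c1p, pos["C2'"], 1.53, 102.0, 35.0)
    pos["O3'"] = place_atom(c1p, pos["C2'"], pos["C3'"], 1.42, 110.0, -60.0)
    pos["C5'"] = place_atom(c1p, o4p, c4p, 1.51, 109.0, -120.0)
    pos["O5'"] = place_atom(o4p, c4p, pos["C5'"], 1.44, 111.0, 180.0)
    if cyclic_phosphate:
        pos["P"] = place_atom(c4p, pos["C5'"], pos["O5'"], 1.60, 120.0, 180.0)
        pos["O1P"] = place_atom(pos["C5'"], pos["O5'"], pos["P"], 1.48, 110.0, 60.0)
        pos["O2P"] = place_atom(pos["C5'"], pos["O5'"], pos["P"], 1.48, 110.0, -60.0)

    name = {"guanine": "PCG", "adenine": "CMP"}[base] if cyclic_phosphate else \
           {"guanine": "5GP", "adenine": "AMP"}[base]
    atoms = [_mk_atom(an, p, i + 1) for i, (an, p) in enumerate(pos.items())]
    return Residue(name=name, seq_number=seq_number, is_hetero=True, atoms=atoms)


def nucleotide_model(chi: float, base: str = "guanine",
                     cyclic_phosphate: bool = True) -> StructureModel:
    """Single-ligand model wrapping :func:`build_purine_nucleotide`."""
    lig = build_purine_nucleotide(chi, base, cyclic_phosphate)
    return StructureModel(chains=[Chain(chain_id="L", residues=[lig])],
                          source_id=f"nucleotide_chi{chi:+.1f}")


# ---------------------------------------------------------------------------
# perturbed copies

def random_rotation_translation(seed: int, max_shift: float = 20.0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def perturb_chain(
    model: StructureModel,
    sigma: float,
    transform: Union[str, tuple, None] = "random",
    seed: int = 0,
) -> StructureModel:
    """Copy of *model* with Gaussian coordinate noise then a rigid motion.

    sigma is the isotropic per-coordinate displacement in Angstrom;
    *transform* is ``"random"`` (seeded), ``None``/``"identity"``, or an
    explicit ``(R, t)`` pair.  Deterministic per seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if transform == "random":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
    elif transform in (None, "identity"):
        R, t = np.eye(3), np.zeros(3)
    else:
        R, t = transform
        R = np.asarray(R, float)
        t = np.asarray(t, float)
    out = copy.deepcopy(model)
    for ch in out.chains:
        for res in ch.residues:
            for atom in res.atoms:
                p = atom.position
                if sigma > 0:
                    p = p + rng.normal(0.0, sigma, size=3)
                atom.position = R @ p + t
    out.source_id = f"{model.source_id}_perturbed_s{sigma}_seed{seed}"
    return out


# ---------------------------------------------------------------------------
# titrations

def noisy_titration(
    params: OneSiteParams,
    design: TitrationDesign,
    heat_sigma: float,
    seed: int,
) -> TitrationCurve:
    """One-site titration with i.i.d. Gaussian noise (ucal) on each heat."""
    if heat_sigma < 0:
        raise ValueError("heat_sigma must be non-negative")
    clean = simulate_titration(params, design)
    if heat_sigma == 0:
        return clean
    rng = np.random.default_rng(seed)
    heats = clean.heats + rng.normal(0.0, heat_sigma, size=len(clean.heats))
    injected = np.asarray(design.injection_volumes) * design.syringe_concentration
    normalized = (heats * 1e-6 / injected) / 1000.0
    return TitrationCurve(molar_ratio=clean.molar_ratio, heats=heats, normalized=normalized)


# ---------------------------------------------------------------------------
# fixture specs

@dataclass
class FixtureSpec:
    """Declarative fixture recipe; identical specs give identical output."""
    kind: str                       # dipeptide | purine_nucleotide | chain_copy | titration
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self):
        p = dict(self.parameters)
        if self.kind == "dipeptide":
            return build_dipeptide(float(p.get("omega", 180.0)),
                                   tuple(p.get("residue_names", ("ALA", "ALA"))))
        if self.kind == "purine_nucleotide":
            return nucleotide_model(float(p.get("chi", 45.0)),
                                    p.get("base", "guanine"),
                                    bool(p.get("cyclic_phosphate", True)))
        if self.kind == "chain_copy":
            base = build_polyalanine(int(p.get("n_residues", 12)))
            return perturb_chain(base, float(p.get("sigma", 0.0)),
                                 p.get("transform", "random"), self.seed)
        if self.kind == "titration":
            params = OneSiteParams(n=float(p.get("n", 1.0)),
                                   Ka=float(p.get("Ka", 1e7)),
                                   dH=float(p.get("dH", -12000.0)))
            design = TitrationDesign(
                cell_concentration=float(p.get("cell_concentration", 15e-6)),
                syringe_concentration=float(p.get("syringe_concentration", 250e-6)),
                injection_volumes=[float(p.get("injection_volume", 5e-6))]
                * int(p.get("n_injections", 28)),
                cell_volume=float(p.get("cell_volume", 1.43e-3)),
                temperature=float(p.get("temperature", 303.15)),
            )
            return noisy_titration(params, design, float(p.get("heat_sigma", 0.0)), self.seed)
        raise ValueError(f"unknown fixture kind {self.kind!r}")
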
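"""Coordinate I/O, atom selection and crystal-level quantities.

Parsing of PDB and mmCIF dialects is delegated to gemmi; this module only
converts gemmi's hierarchy into the package's :class:`~cnbdkit.model`
containers, so the rest of the pipeline never touches format details.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Optional, Union

import gemmi

from .model import Atom, Chain, CrystalInfo, Residue, StructureModel

logger = logging.getLogger(__name__)

#: space groups expected in hexagonal / tetragonal CNBD crystal forms;
#: kept for documentation — multiplicity is resolved from gemmi's tables.
KNOWN_SPACE_GROUPS = {"P 62 2 2": 12, "P 43": 4, "P 21 21 21": 4, "P 1": 1, "C 2": 4}

#: residue-name dialects for the cyclic nucleotides across depositions
CGMP_NAMES = frozenset({"PCG", "CGM", "35G", "CGP"})
CAMP_NAMES = frozenset({"CMP", "CAM", "1CA"})

#: Matthews constant: inverse protein partial specific volume term, A^3/Da
MATTHEWS_PROTEIN_DENSITY = 1.23

#: mean residue mass used when no sequence is available, Da
MEAN_RESIDUE_MASS = 110.0


class ParseError(ValueError):
    """Malformed coordinate input."""


def space_group_multiplicity(hm_symbol: str) -> int:
    """Number of symmetry operators of a space group (Hermann–Mauguin)."""
    sg = gemmi.find_spacegroup_by_name(hm_symbol)
    if sg is None:
        raise ValueError(f"unknown space group {hm_symbol!r}")
    return len(sg.operations())


def _convert(st: gemmi.Structure, source_id: str) -> StructureModel:
    chains: list[Chain] = []
    if len(st) == 0:
        return StructureModel(chains=[], crystal=_crystal_of(st), source_id=source_id)
    model = st[0]
    for gch in model:
        residues: list[Residue] = []
        for gres in gch:
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=[ga.pos.x, ga.pos.y, ga.pos.z],
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    b_factor=max(ga.b_iso, 0.0),
                    alt_loc=ga.altloc.strip() if ga.altloc != "\x00" else "",
                    serial=ga.serial,
                )
                for ga in gres
            ]
            residues.append(
                Residue(
                    name=gres.name,
                    seq_number=gres.seqid.num,
                    insertion_code=(gres.seqid.icode or "").strip(),
                    is_hetero=(gres.het_flag == "H"),
                    atoms=atoms,
                )
            )
        chains.append(Chain(chain_id=gch.name, residues=residues))
    return StructureModel(chains=chains, crystal=_crystal_of(st), source_id=source_id)


def _crystal_of(st: gemmi.Structure) -> Optional[CrystalInfo]:
    cell = st.cell
    if not cell.is_crystal():
        return None
    sg = st.spacegroup_hm or ""
    mult = None
    if sg:
        try:
            mult = space_group_multiplicity(sg)
        except ValueError:
            logger.warning("space group %r not in symmetry tables", sg)
    return CrystalInfo(
        a=cell.a, b=cell.b, c=cell.c,
        alpha=cell.alpha, beta=cell.beta, gamma=cell.gamma,
        space_group=sg, asu_multiplicity=mult,
    )


def read_structure(source: Union[str, os.PathLike], fmt: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file (or a string holding its text).

    Parameters
    ----------
    source:
        Path to a coordinate file, or the file's full text (detected by the
        presence of newlines).
    fmt:
        ``"pdb"``, ``"mmcif"`` or ``"auto"``.
    """
    if fmt not in {"pdb", "mmcif", "auto"}:
        raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")
    is_text = isinstance(source, str) and "\n" in source
    try:
        if is_text:
            text = source
            if fmt == "mmcif" or (fmt == "auto" and text.lstrip().startswith("data_")):
                doc = gemmi.cif.read_string(text)
                st = gemmi.make_structure_from_block(doc.sole_block())
                source_id = doc.sole_block().name
            else:
                st = gemmi.read_pdb_string(text)
                source_id = st.name or "<string>"
        else:
            path = os.fspath(source)
            if not os.path.exists(path):
                raise FileNotFoundError(path)
            if fmt == "auto":
                st = gemmi.read_structure(path)
            elif fmt == "pdb":
                st = gemmi.read_pdb(path)
            else:
                doc = gemmi.cif.read(path)
                st = gemmi.make_structure_from_block(doc.sole_block())
            source_id = st.name or os.path.splitext(os.path.basename(path))[0]
    except (FileNotFoundError, IsADirectoryError):
        raise
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse coordinate input: {exc}") from exc
    st.setup_entities()
    return _convert(st, source_id)


def write_pdb(model: StructureModel, path: Union[str, os.PathLike, None] = None) -> str:
    """Serialize a model to PDB text; optionally write it to *path*."""
    st = gemmi.Structure()
    st.name = model.source_id or "model"
    if model.crystal is not None:
        cr = model.crystal
        st.cell = gemmi.UnitCell(cr.a, cr.b, cr.c, cr.alpha, cr.beta, cr.gamma)
        st.spacegroup_hm = cr.space_group or "P 1"
    gm = gemmi.Model("1")
    serial = 0
    for chain in model.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "H" if res.is_hetero else "A"
            for atom in res.atoms:
                serial += 1
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.b_factor
                ga.altloc = atom.alt_loc or "\x00"
                ga.serial = atom.serial or serial
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def select_atoms(
    model: StructureModel,
    chain_id: Optional[str] = None,
    seq_number: Union[int, Iterable[int], None] = None,
    res_name: Union[str, Iterable[str], None] = None,
    atom_name: Union[str, Iterable[str], None] = None,
    hetero: Optional[bool] = None,
    include_altloc: bool = False,
) -> list[tuple[Chain, Residue, Atom]]:
    """Atoms matching all given criteria, in model order.

    A contradictory selector simply yields an empty list. Alternate
    locations are collapsed to the preferred conformer unless
    *include_altloc* is set.
    """
    def as_set(x):
        if x is None:
            return None
        if isinstance(x, (str, int)):
            return {x}
        return set(x)

    from .model import normalize_atom_name as _norm

    seqs = as_set(seq_number)
    rnames = as_set(res_name)
    anames = as_set(atom_name)
    if anames is not None:
        anames = {_norm(str(a)) for a in anames}

    out: list[tuple[Chain, Residue, Atom]] = []
    for ch in model.chains:
        if chain_id is not None and ch.chain_id != chain_id:
            continue
        for res in ch.residues:
            if seqs is not None and res.seq_number not in seqs:
                continue
            if rnames is not None and res.name not in rnames:
                continue
            if hetero is not None and res.is_hetero != hetero:
                continue
            atoms = res.atoms if include_altloc else res.preferred_atoms()
            for atom in atoms:
                if anames is not None and atom.key not in anames:
                    continue
                out.append((ch, res, atom))
    return out


def cell_volume(crystal: CrystalInfo) -> float:
    """Unit-cell volume (A^3) by the general triclinic formula."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (crystal.alpha, crystal.beta, crystal.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0:
        raise ValueError("degenerate unit cell")
    return crystal.a * crystal.b * crystal.c * math.sqrt(arg)


def matthews_solvent(
    crystal: CrystalInfo,
    molecules_per_asu: int,
    molecular_weight: float,
) -> tuple[float, float, float]:
    """Matthews coefficient and solvent fraction of a crystal form.

    Returns ``(cell_volume A^3, V_M A^3/Da, solvent_fraction)`` with
    ``V_M = V_cell / (Z_sym * n_mol * MW)`` and solvent fraction
    ``1 - 1.23 / V_M`` (protein partial specific volume convention).
    """
    if molecules_per_asu <= 0 or molecular_weight <= 0:
        raise ValueError("molecules_per_asu and molecular_weight must be positive")
    mult = crystal.asu_multiplicity
    if mult is None:
        if not crystal.space_group:
            raise ValueError("crystal has neither asu_multiplicity nor a space group")
        mult = space_group_multiplicity(crystal.space_group)
    vol = cell_volume(crystal)
    vm = vol / (mult * molecules_per_asu * molecular_weight)
    solvent = 1.0 - MATTHEWS_PROTEIN_DENSITY / vm
    return vol, vm, solvent


def approximate_protein_mw(n_residues: int, mean_residue_mass: float = MEAN_RESIDUE_MASS) -> float:
    """Protein MW estimate from residue count (plus one water for termini)."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return n_residues * mean_residue_mass + 18.0
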
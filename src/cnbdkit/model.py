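"""Hierarchical coordinate model: Atom -> Residue -> Chain -> StructureModel.

The container is deliberately minimal: author-assigned residue numbering is
preserved verbatim (the crystallographic literature labels contacts by it),
alternate locations are retained on read, and geometry code asks a residue
for its *preferred* conformer (highest occupancy, ties broken alphabetically
by alt-loc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: characters that PDB dialects use interchangeably for the prime in
#: ribose atom names (O2* == O2' == O2′)
_PRIME_CHARS = {"*": "'", "′": "'", "´": "'"}


def normalize_atom_name(name: str) -> str:
    """Collapse prime-character spelling variants of an atom name.

    ``O2*``, ``O2'`` and ``O2′`` all map to ``O2'``.
    """
    out = name.strip()
    for bad, good in _PRIME_CHARS.items():
        out = out.replace(bad, good)
    return out


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name}: negative B-factor {self.b_factor}")

    @property
    def key(self) -> str:
        """Normalized atom-name key used for all lookups."""
        return normalize_atom_name(self.name)


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str = ""
    is_hetero: bool = False
    atoms: list[Atom] = field(default_factory=list)

    @property
    def id(self) -> str:
        return f"{self.name}{self.seq_number}{self.insertion_code}"

    def atom(self, name: str) -> Optional[Atom]:
        """Return the preferred conformer of the named atom, or None.

        Preference: highest occupancy; ties broken by alphabetical alt_loc
        (blank alt_loc sorts first), so the choice is deterministic.
        """
        key = normalize_atom_name(name)
        candidates = [a for a in self.atoms if a.key == key]
        if not candidates:
            return None
        return min(candidates, key=lambda a: (-a.occupancy, a.alt_loc))

    def preferred_atoms(self) -> list[Atom]:
        """All atoms after alt-loc filtering (one conformer per atom name)."""
        seen: dict[str, Atom] = {}
        for a in self.atoms:
            prev = seen.get(a.key)
            if prev is None or (-a.occupancy, a.alt_loc) < (-prev.occupancy, prev.alt_loc):
                seen[a.key] = a
        # preserve file order of the retained conformers
        kept = set(id(a) for a in seen.values())
        return [a for a in self.atoms if id(a) in kept]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seq_number: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.seq_number == seq_number and r.insertion_code == insertion_code:
                return r
        return None

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class CrystalInfo:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = ""
    z_asu: Optional[int] = None
    asu_multiplicity: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {ang} outside (0, 180)")
        if self.asu_multiplicity is not None and self.asu_multiplicity < 1:
            raise ValueError("asu_multiplicity must be >= 1")


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    crystal: Optional[CrystalInfo] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        ids = [c.chain_id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate chain ids: {ids}")

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def all_atoms(self) -> list[tuple[Chain, Residue, Atom]]:
        out = []
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    out.append((c, r, a))
        return out

    def hetero_residues(self, names: Optional[Sequence[str]] = None) -> list[tuple[Chain, Residue]]:
        """Hetero residues, optionally restricted to a residue-name set."""
        wanted = set(names) if names is not None else None
        out = []
        for c in self.chains:
            for r in c.residues:
                if r.is_hetero and (wanted is None or r.name in wanted):
                    out.append((c, r))
        return out
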
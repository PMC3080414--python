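"""Run configuration shared by the CLI and report writers.

Defaults mirror the geometry/superposition/ITC module constants; every
value can be overridden from a plain-text ``key = value`` file or the
command line, and the effective configuration is echoed into every report
so a run is self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from . import geometry, itc, superpose
from .io import CAMP_NAMES, CGMP_NAMES

#: default secondary-structure spans (author numbering of the 92–227
#: construct) used for B-factor region means; the beta4/beta5 hairpin is
#: the mobile purine-docking region, the rest are the helical elements.
DEFAULT_REGIONS = {
    "beta4_beta5": (161, 176),
    "alphaXN": (97, 106),
    "alphaA": (107, 118),
    "P_helix": (181, 186),
    "alphaB": (199, 212),
}


@dataclass
class RunConfig:
    hbond_cutoff: float = geometry.HBOND_CUTOFF
    vdw_cutoff: float = geometry.VDW_CUTOFF
    cis_window: float = geometry.CIS_WINDOW
    syn_window: float = geometry.SYN_WINDOW
    disulfide_cutoff: float = geometry.DISULFIDE_CUTOFF
    reject_cutoff: float = superpose.REJECT_CUTOFF
    max_cycles: int = superpose.MAX_CYCLES
    restraint_threshold: float = superpose.RESTRAINT_THRESHOLD
    cell_volume: float = itc.DEFAULT_CELL_VOLUME
    temperature: float = itc.DEFAULT_TEMPERATURE
    gas_constant: float = itc.R_CAL
    cgmp_names: tuple = tuple(sorted(CGMP_NAMES))
    camp_names: tuple = tuple(sorted(CAMP_NAMES))
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    output_dir: str = "."
    seed: int = 0

    @property
    def ligand_names(self) -> set:
        return set(self.cgmp_names) | set(self.camp_names)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {k: list(v) for k, v in d["regions"].items()}
        return d

    @classmethod
    def from_file(cls, path: Optional[str] = None, **overrides) -> "RunConfig":
        """Build a config from an optional ``key = value`` file plus
        keyword overrides (overrides win)."""
        values: dict = {}
        if path is not None:
            for lineno, raw in enumerate(open(path), start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, val = (s.strip() for s in line.split("=", 1))
                values[key] = val
        cfg = cls()
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in {**values, **overrides}.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(val, str):
                if isinstance(current, bool):
                    val = val.lower() in ("1", "true", "yes")
                elif isinstance(current, int) and not isinstance(current, bool):
                    val = int(val)
                elif isinstance(current, float):
                    val = float(val)
            setattr(cfg, key, val)
        return cfg
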
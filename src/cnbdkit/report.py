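"""Report writers: TSV contact/torsion/B-factor tables and JSON summaries.

Every JSON report embeds the package version, the effective configuration,
input checksums and the seed, so identical inputs reproduce identical
reports (timestamps are omitted by design).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Iterable, Optional

import numpy as np

from .config import RunConfig
from .geometry import BFactorProfile, ContactRecord, PeptideLink, TorsionRecord

try:
    from importlib.metadata import version as _pkg_version
    VERSION = _pkg_version("cnbdkit")
except Exception:  # pragma: no cover - not installed
    VERSION = "unknown"


def sha256_of(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def report_envelope(config: RunConfig, inputs: Iterable[str] = (), **payload) -> dict:
    return {
        "tool": "cnbdkit",
        "version": VERSION,
        "config": config.as_dict(),
        "inputs": {os.path.basename(p): sha256_of(p) for p in inputs if os.path.exists(p)},
        "seed": config.seed,
        **{k: _jsonable(v) for k, v in payload.items()},
    }


def write_json(report: dict, path: Optional[str]) -> str:
    text = json.dumps(report, indent=2, sort_keys=False) + "\n"
    if path:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def contacts_tsv(records: Iterable[ContactRecord]) -> str:
    lines = ["chain\tresidue\tprotein_atom\tligand_atom\tdistance_A\tclass\textended\tsite"]
    for r in records:
        lines.append(
            f"{r.chain_id}\t{r.residue}\t{r.protein_atom}\t{r.ligand_atom}"
            f"\t{r.distance:.2f}\t{r.contact_class}\t{int(r.extended)}\t{r.site_label}"
        )
    return "\n".join(lines) + "\n"


def torsions_tsv(records: Iterable[TorsionRecord]) -> str:
    lines = ["kind\tlocus\tangle_deg\tclassification"]
    for r in records:
        lines.append(f"{r.kind}\t{r.locus}\t{r.angle:.2f}\t{r.classification}")
    return "\n".join(lines) + "\n"


def omega_tsv(links: Iterable[PeptideLink]) -> str:
    lines = ["residue_i\tresidue_i+1\tomega_deg\tclass\tproline"]
    for l in links:
        lines.append(
            f"{l.residue_i}\t{l.residue_iplus1}\t{l.omega:.2f}"
            f"\t{l.classification}\t{int(l.involves_proline)}"
        )
    return "\n".join(lines) + "\n"


def bfactor_tsv(profile: BFactorProfile) -> str:
    lines = ["seq_number\tca_bfactor"]
    for seq, b in profile.entries:
        lines.append(f"{seq}\t{b:.2f}")
    return "\n".join(lines) + "\n"
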
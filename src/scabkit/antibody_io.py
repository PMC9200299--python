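"""Reading, writing and encoding of paired heavy/light antibody Fv records.

An :class:`FvRecord` stores the concatenated heavy-then-light variable
domains: sequences, Chothia-style per-residue numbering (number + insertion
code), and per-residue heavy-atom coordinates.  Absent atoms are simply not
present in a residue's atom map — presence is always explicit, coordinates are
never zero-filled.

PDB parsing goes through Bio.PDB (first model, altloc resolved to the highest
occupancy); numbering is taken as given in the file, as antibody structure
databases distribute Chothia-numbered coordinates.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

from .constants import (AA_INDEX, CHOTHIA_CDRS, ONE_TO_THREE, THREE_TO_ONE,
                        atom_element, heavy_atoms)

_RES_RE = re.compile(r"REMARK   2 RESOLUTION\.\s+([0-9]+\.?[0-9]*)\s+ANGSTROM")


@dataclass
class FvRecord:
    """Paired heavy/light Fv with optional coordinates.

    ``numbering`` holds one ``(chain, number, insertion_code)`` triple per
    residue, heavy residues first; ``atoms`` holds one ``{atom_name: xyz}``
    map per residue.  ``meta`` carries generator ground truth (torsion draws,
    region annotation) for synthetic records and is not used by readers.
    """

    name: str
    heavy_seq: str
    light_seq: str
    numbering: list[tuple[str, int, str]]
    atoms: list[dict[str, np.ndarray]] | None = None
    resolution: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        L = len(self.heavy_seq) + len(self.light_seq)
        if len(self.numbering) != L:
            raise ValueError(f"numbering length {len(self.numbering)} != L={L}")
        if self.atoms is not None and len(self.atoms) != L:
            raise ValueError("atoms list length mismatch")

    # -- basic views --------------------------------------------------------
    @property
    def sequence(self) -> str:
        return self.heavy_seq + self.light_seq

    @property
    def L(self) -> int:
        return len(self.heavy_seq) + len(self.light_seq)

    @property
    def heavy_len(self) -> int:
        return len(self.heavy_seq)

    def res3(self, i: int) -> str:
        return ONE_TO_THREE[self.sequence[i]]

    def coords(self, atom: str) -> tuple[np.ndarray, np.ndarray]:
        """Coordinates of one named atom for every residue.

        Returns ``(xyz, present)`` with xyz (L, 3) float (NaN where absent)
        and a boolean presence flag per residue.
        """
        if self.atoms is None:
            raise ValueError(f"record {self.name!r} carries no coordinates")
        xyz = np.full((self.L, 3), np.nan)
        present = np.zeros(self.L, dtype=bool)
        for i, amap in enumerate(self.atoms):
            if atom in amap:
                xyz[i] = amap[atom]
                present[i] = True
        return xyz, present

    def has_atom(self, i: int, atom: str) -> bool:
        return self.atoms is not None and atom in self.atoms[i]

    @property
    def region(self) -> list[str]:
        """Per-residue region tag (FR or one of the six CDRs)."""
        masks = region_masks(self)
        tags = np.array(["FR"] * self.L, dtype=object)
        for name, mask in masks.items():
            if name != "FR":
                tags[mask] = name
        return list(tags)


@dataclass
class InputEncoding:
    onehot: np.ndarray     # (L, 20)
    delimiter: np.ndarray  # (L, 1)
    combined: np.ndarray   # (L, 21)


# ---------------------------------------------------------------------------
# PDB I/O

def _icode_key(icode: str) -> str:
    return "" if icode in (" ", "") else icode


def read_fv_structure(pdb_text: str, heavy_id: str = "H", light_id: str = "L",
                      name: str = "fv") -> FvRecord:
    """Parse a two-chain Fv from PDB text.

    Residues are ordered heavy-then-light and, within each chain, by
    (residue number, insertion code).  Alternate locations resolve to the
    highest-occupancy conformer (ties keep the first in file, Bio.PDB's
    behaviour).  Only the first model of multi-model files is read.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("fv", io.StringIO(pdb_text))
    model = next(structure.get_models())
    chains = {c.id: c for c in model}
    for cid, label in ((heavy_id, "heavy"), (light_id, "light")):
        if cid not in chains:
            raise ValueError(f"{label} chain {cid!r} not found in PDB "
                             f"(chains present: {sorted(chains)})")

    seqs: dict[str, str] = {}
    numbering: list[tuple[str, int, str]] = []
    atoms: list[dict[str, np.ndarray]] = []
    for cid, tag in ((heavy_id, "H"), (light_id, "L")):
        residues = [r for r in chains[cid]
                    if is_aa(r, standard=False) and r.get_resname() in THREE_TO_ONE]
        residues.sort(key=lambda r: (r.id[1], _icode_key(r.id[2])))
        seq = []
        for r in residues:
            seq.append(THREE_TO_ONE[r.get_resname()])
            numbering.append((tag, r.id[1], _icode_key(r.id[2])))
            amap = {}
            for a in r.get_atoms():  # DisorderedAtom yields the selected altloc
                amap[a.get_name()] = np.array(a.get_coord(), dtype=float)
            atoms.append(amap)
        seqs[tag] = "".join(seq)
    if not seqs["H"] or not seqs["L"]:
        empty = "heavy" if not seqs["H"] else "light"
        raise ValueError(f"zero residues parsed for the {empty} chain")

    m = _RES_RE.search(pdb_text)
    resolution = float(m.group(1)) if m else None
    return FvRecord(name=name, heavy_seq=seqs["H"], light_seq=seqs["L"],
                    numbering=numbering, atoms=atoms, resolution=resolution)


def write_fv_pdb(record: FvRecord) -> str:
    """Serialize a record with coordinates to PDB text (heavy chain H, light L)."""
    if record.atoms is None:
        raise ValueError("record has no coordinates to write")
    lines = []
    if record.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {record.resolution:6.2f} ANGSTROMS.")
    serial = 1
    prev_chain = None
    for i in range(record.L):
        chain, num, icode = record.numbering[i]
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        res3 = record.res3(i)
        for aname in heavy_atoms(res3):
            if aname not in record.atoms[i]:
                continue
            x, y, z = record.atoms[i][aname]
            pdb_name = aname if len(aname) == 4 else f" {aname:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{res3:<3s} {chain}"
                f"{num:4d}{icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {atom_element(aname):>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fv_fasta(text: str) -> tuple[str, str, str]:
    """Read paired sequences from FASTA with ids ``<name>_H`` and ``<name>_L``.

    Returns (name, heavy_seq, light_seq).
    """
    from Bio import SeqIO
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    seqs = {}
    base = None
    for rec in records:
        if rec.id.endswith("_H") or rec.id.endswith("_L"):
            base = rec.id[:-2]
            seqs[rec.id[-1]] = str(rec.seq)
    if "H" not in seqs or "L" not in seqs:
        raise ValueError("FASTA must contain records named <name>_H and <name>_L")
    return base or "fv", seqs["H"], seqs["L"]


def write_fv_fasta(record: FvRecord) -> str:
    return (f">{record.name}_H\n{record.heavy_seq}\n"
            f">{record.name}_L\n{record.light_seq}\n")


# ---------------------------------------------------------------------------
# model input encoding

def encode_sequence(record: FvRecord) -> InputEncoding:
    """One-hot encode the concatenated Fv sequence plus a chain-break column.

    The delimiter column is 1 only at the last heavy-chain residue, giving a
    combined input of shape (L, 21).
    """
    L = record.L
    onehot = np.zeros((L, 20))
    for i, aa in enumerate(record.sequence):
        if aa not in AA_INDEX:
            raise ValueError(f"non-canonical residue {aa!r} at position {i}")
        onehot[i, AA_INDEX[aa]] = 1.0
    delim = np.zeros((L, 1))
    delim[record.heavy_len - 1, 0] = 1.0
    return InputEncoding(onehot=onehot, delimiter=delim,
                         combined=np.concatenate([onehot, delim], axis=1))


# ---------------------------------------------------------------------------
# Chothia regions

def load_cdr_boundaries(path) -> dict[str, tuple[str, int, int]]:
    """Load CDR boundary overrides from a YAML file.

    Format: ``CDR-H1: {chain: H, start: 26, stop: 32}`` per region; regions
    not listed keep their built-in Chothia window.
    """
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(CHOTHIA_CDRS)
    for region, spec in raw.items():
        if region not in out:
            raise ValueError(f"unknown region {region!r}")
        out[region] = (spec["chain"], int(spec["start"]), int(spec["stop"]))
    return out


def region_masks(record: FvRecord,
                 boundaries: dict[str, tuple[str, int, int]] | None = None
                 ) -> dict[str, np.ndarray]:
    """Boolean masks over L for FR and the six CDRs (a partition of L).

    CDR membership is decided from the Chothia residue number of each
    position; insertion codes inherit the membership of their base number.
    """
    if not record.numbering:
        raise ValueError("record carries no numbering")
    bounds = boundaries or CHOTHIA_CDRS
    masks = {name: np.zeros(record.L, dtype=bool) for name in bounds}
    for i, (chain, num, _icode) in enumerate(record.numbering):
        for name, (bchain, lo, hi) in bounds.items():
            if chain == bchain and lo <= num <= hi:
                masks[name][i] = True
                break
    masks["FR"] = ~np.any(np.stack(list(masks.values())), axis=0)
    return masks
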
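"""Readers and writers for the standard formats the pipeline consumes.

FASTA goes through Biopython; coordinate files (PDB and mmCIF) go through
gemmi.  Structures are returned as plain ``gemmi.Structure`` objects after
normalisation: alternate conformations are reduced to the highest-occupancy
altloc (ties resolved toward 'A'), and the id/resolution fields are filled
from the file header.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
from Bio import SeqIO

from .motif import MotifHit, ProteinRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_structure",
    "read_structure_dir",
    "write_structure",
    "hits_to_tsv",
    "parse_fasta_id",
]


def parse_fasta_id(raw: str) -> str:
    """First whitespace token; UniProt ``db|ACC|name`` headers yield ACC."""
    token = raw.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "-" in seq or "*" in seq:
            warnings.warn(
                f"{rec.id}: stripped gap/stop characters from sequence",
                stacklevel=2,
            )
            seq = seq.replace("-", "").replace("*", "")
        records.append(
            ProteinRecord(
                id=parse_fasta_id(rec.description or rec.id),
                sequence=seq,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _prune_altlocs(structure: gemmi.Structure) -> None:
    """Keep one conformation per atom name: highest occupancy, ties -> 'A'."""
    for model in structure:
        for chain in model:
            for residue in chain:
                by_name: dict[str, list] = {}
                for atom in residue:
                    by_name.setdefault(atom.name, []).append(atom)
                doomed = []
                for atoms in by_name.values():
                    if len(atoms) > 1:
                        keep = max(atoms, key=lambda a: (a.occ, a.altloc in ("", "A")))
                        doomed.extend(a for a in atoms if a is not keep)
                for atom in doomed:
                    for i in range(len(residue) - 1, -1, -1):
                        if residue[i] is atom:
                            del residue[i]
                            break


def read_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if not st.name:
        st.name = Path(path).stem
    _prune_altlocs(st)
    return st


def read_structure_dir(directory: str | Path, patterns=("*.pdb", "*.cif", "*.ent")) -> list[gemmi.Structure]:
    """Read every coordinate file in a directory; unreadable files warn and skip."""
    structures = []
    paths: list[Path] = []
    for pat in patterns:
        paths.extend(sorted(Path(directory).glob(pat)))
    for p in paths:
        try:
            structures.append(read_structure(p))
        except Exception as exc:  # per-file failure must not abort the batch
            warnings.warn(f"could not read {p}: {exc}", stacklevel=2)
    return structures


def write_structure(structure: gemmi.Structure, path: str | Path) -> None:
    path = str(path)
    if path.endswith(".cif"):
        structure.make_mmcif_document().write_file(path)
    else:
        structure.write_pdb(path)


_TSV_COLUMNS = (
    "protein_id",
    "start",
    "end",
    "phospho_pos",
    "anchor_pos",
    "gap_len",
    "spacing",
    "matched_seq",
)


def hits_to_tsv(hits: Iterable[MotifHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.protein_id,
                        h.start,
                        h.end,
                        h.phospho_pos,
                        h.anchor_pos,
                        h.gap_len,
                        h.spacing,
                        h.matched_seq,
                    )
                )
                + "\n"
            )
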
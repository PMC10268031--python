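"""Readers and writers for the dataset's on-disk formats.

Molecule table: TSV ``molecule_id<TAB>smiles`` (header optional).
miRNA sequences: FASTA; the record ID up to the first whitespace is the miRNA
ID; case-insensitive, T read as U.
Association list: TSV ``molecule_id<TAB>mirna_id[<TAB>label]``; a missing
label column means every row is a positive.

Writers emit a canonical form (sorted, uppercase-U sequences) so that a
read -> write round trip is byte-stable.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_MOLECULE_HEADER = ("molecule_id", "smiles")
_ASSOC_HEADER = ("molecule_id", "mirna_id", "label")


def read_molecule_table(path):
    """id -> SMILES from a two-column TSV; header row is skipped if present."""
    molecules = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and tuple(p.lower() for p in parts) == _MOLECULE_HEADER:
                continue
            mol_id, smiles = parts[0].strip(), parts[1].strip()
            if mol_id in molecules:
                raise ValueError(f"{path}:{lineno}: duplicate molecule ID {mol_id!r}")
            molecules[mol_id] = smiles
    return molecules


def write_molecule_table(molecules, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_MOLECULE_HEADER) + "\n")
        for mol_id in sorted(molecules):
            fh.write(f"{mol_id}\t{molecules[mol_id]}\n")


def read_mirna_fasta(path):
    """id -> RNA sequence (uppercased, T mapped to U)."""
    mirnas = {}
    for record in SeqIO.parse(path, "fasta"):
        mirna_id = record.id
        if mirna_id in mirnas:
            raise ValueError(f"{path}: duplicate miRNA ID {mirna_id!r}")
        mirnas[mirna_id] = str(record.seq).upper().replace("T", "U")
    if not mirnas:
        raise ValueError(f"{path}: no FASTA records found")
    return mirnas


def write_mirna_fasta(mirnas, path):
    records = [
        SeqRecord(Seq(mirnas[mid].upper().replace("T", "U")), id=mid, description="")
        for mid in sorted(mirnas)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def read_associations(path):
    """List of (molecule_id, mirna_id, label); label defaults to 1."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns")
            low = tuple(p.lower() for p in parts)
            if lineno == 1 and low in (_ASSOC_HEADER, _ASSOC_HEADER[:2]):
                continue
            label = 1
            if len(parts) == 3:
                if parts[2] not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1")
                label = int(parts[2])
            pairs.append((parts[0].strip(), parts[1].strip(), label))
    return pairs


def write_associations(pairs, path, with_labels=True):
    with open(path, "w", encoding="utf-8") as fh:
        if with_labels:
            fh.write("\t".join(_ASSOC_HEADER) + "\n")
            for mol_id, mirna_id, label in sorted(pairs):
                fh.write(f"{mol_id}\t{mirna_id}\t{int(label)}\n")
        else:
            fh.write("\t".join(_ASSOC_HEADER[:2]) + "\n")
            for mol_id, mirna_id in sorted(pairs):
                fh.write(f"{mol_id}\t{mirna_id}\n")
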
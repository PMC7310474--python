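"""Gapped FASTA alignment I/O with UniProt-style header parsing.

The alignments handled here are protein multiple sequence alignments in
plain FASTA text: equal-length rows over the 20 amino acids plus ``X``
(unknown residue, tolerated at parse time, rejected later by curation)
and the gap character. ``.`` is accepted as a gap on input and normalised
to ``-``; residues are uppercased. Headers in the UniProt dialect
``db|ACCESSION|ENTRY_MNEMONIC`` are decomposed so downstream modules can
key on the organism mnemonic (the suffix after the last underscore of the
entry name, e.g. ``HUMAN`` or ``9TELE``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
#: Characters legal in an aligned residue string.
RESIDUE_ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS) | {"X", GAP}


class AlignmentFormatError(ValueError):
    """Malformed FASTA input: empty file, illegal character, bad header."""


class AlignmentShapeError(ValueError):
    """Sequences of unequal length where an alignment is required."""


def parse_header(header: str) -> tuple[str, str, str, str]:
    """Decompose a FASTA header (text after ``>``) into UniProt-style parts.

    Returns ``(db, accession, entry_name, mnemonic)``. Headers with three
    ``|``-separated fields in the first whitespace token are treated as
    UniProt-style; anything else degrades to ``db="other"`` with the whole
    token as accession and empty entry name/mnemonic.
    """
    token = header.split()[0] if header.strip() else ""
    parts = token.split("|")
    if len(parts) == 3:
        db = parts[0] if parts[0] in ("sp", "tr") else "other"
        entry_name = parts[2]
        mnemonic = entry_name.rsplit("_", 1)[-1] if "_" in entry_name else ""
        return db, parts[1], entry_name, mnemonic
    return "other", token, "", ""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned (or, for curation input, unaligned) protein sequence."""

    id: str
    residues: str
    db: str = "other"
    accession: str = ""
    entry_name: str = ""
    mnemonic: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentFormatError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in RESIDUE_ALPHABET:
                raise AlignmentFormatError(
                    f"record {self.id!r}: illegal character {ch!r} at position {i + 1}"
                )

    @classmethod
    def from_header(cls, header: str, residues: str) -> "SequenceRecord":
        """Build a record from raw header text and a residue string."""
        token = header.split()[0] if header.strip() else ""
        note = header[len(token):].strip()
        db, accession, entry_name, mnemonic = parse_header(header)
        return cls(
            id=token,
            residues=residues,
            db=db,
            accession=accession,
            entry_name=entry_name,
            mnemonic=mnemonic,
            source_note=note,
        )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def with_residues(self, residues: str) -> "SequenceRecord":
        return replace(self, residues=residues)


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length collection of gapped sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment must contain at least one record")
        width = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != width:
                raise AlignmentShapeError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {width} (same as {self.records[0].id!r})"
                )

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(f"no record with id {record_id!r}")

    def matrix(self) -> np.ndarray:
        """Residues as an (n_records, n_columns) array of single characters."""
        return np.array([list(r.residues) for r in self.records], dtype="<U1")

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """New alignment restricted to the given 0-based column indices."""
        cols = list(columns)
        recs = tuple(
            rec.with_residues("".join(rec.residues[c] for c in cols))
            for rec in self.records
        )
        return Alignment(recs)

    def take_records(self, indices: Sequence[int]) -> "Alignment":
        return Alignment(tuple(self.records[i] for i in indices))


def _normalise(seq: str, record_id: str) -> str:
    s = seq.upper().replace(".", GAP)
    for i, ch in enumerate(s):
        if ch not in RESIDUE_ALPHABET:
            raise AlignmentFormatError(
                f"record {record_id!r}: illegal character {ch!r} at position {i + 1}"
            )
    return s


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA records without requiring equal lengths (curation input)."""
    path = Path(path)
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalise(str(rec.seq), rec.id)
        out.append(SequenceRecord.from_header(rec.description, residues))
    if not out:
        raise AlignmentFormatError(f"{path}: no FASTA records found")
    return out


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped FASTA alignment, preserving input order.

    Raises :class:`AlignmentShapeError` naming the offending record when
    sequence lengths differ, and :class:`AlignmentFormatError` for empty
    files or illegal characters (with the 1-based position).
    """
    return Alignment(tuple(read_sequences(path)))


def write_alignment(alignment: Alignment, path: str | Path) -> Path:
    """Write an alignment as gapped FASTA (60-column wrap, ``-`` for gaps).

    Round-trips: ``read_alignment(write_alignment(a)) == a``.
    """
    path = Path(path)
    bio = [
        _BioSeqRecord(Seq(rec.residues), id=rec.id, description=rec.source_note)
        for rec in alignment.records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")
    return path
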
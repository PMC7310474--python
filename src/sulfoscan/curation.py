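"""Sequence-assessment prerequisites applied before alignment and analysis.

Candidate (ungapped, mature) sequences are screened by six rules:

R1  explicit exclude list (wrong-protein or splice-variant annotations,
    supplied by the user — cannot be derived from sequence alone);
R2  the family-characteristic cysteine arrangement: an N-terminal cysteine
    cluster motif plus at least two further C-terminal cysteines;
R3  fragment-flagged sequences are rejected;
R4  sequences lacking a signal-peptide annotation — or, on precursor
    input, not starting with methionine — are rejected;
R5  sequences containing unknown residues (``X``) are rejected;
R6  one sequence per (species, gene product): later duplicates rejected.

The default cluster motif ``C-x(2,3)-C-x-C-x(6,12)-C`` covers the
published class II/III spacings and is user-overridable; fragment and
signal-peptide status are input metadata because they come from database
annotation, not from the sequence itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .msa_io import SequenceRecord

#: N-terminal cysteine cluster pattern: C, 2-3 residues, C, 1 residue, C,
#: 6-12 residues, C.
DEFAULT_CLUSTER_MOTIF = r"C.{2,3}C.C.{6,12}C"

#: Minimum number of cysteines required after the cluster motif match.
MIN_C_TERMINAL_CYSTEINES = 2


@dataclass(frozen=True)
class RecordMetadata:
    """Per-record database annotations the rules depend on."""

    is_fragment: bool = False
    has_signal_annotation: bool = True
    is_precursor: bool = False
    gene: str = ""


@dataclass(frozen=True)
class CurationReport:
    kept: tuple[str, ...]
    rejected: tuple[tuple[str, str, str], ...]  # (id, rule, message)

    @property
    def rejected_ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.rejected)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("id\tstatus\trule\tmessage\n")
            rej = {r[0]: r for r in self.rejected}
            for rid in self.kept:
                fh.write(f"{rid}\tkept\t\t\n")
            for rid, rule, msg in self.rejected:
                fh.write(f"{rid}\trejected\t{rule}\t{msg}\n")
        return path


def load_exclude_list(path: str | Path) -> frozenset[str]:
    """Read an exclude list: one sequence id per line, ``#`` comments."""
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.add(line)
    return frozenset(ids)


def _passes_cysteine_motif(sequence: str, motif: str) -> bool:
    m = re.search(motif, sequence)
    if m is None:
        return False
    return sequence[m.end():].count("C") >= MIN_C_TERMINAL_CYSTEINES


def curate(
    records: Sequence[SequenceRecord],
    metadata: Mapping[str, RecordMetadata] | None = None,
    motif: str = DEFAULT_CLUSTER_MOTIF,
    exclude_ids: Iterable[str] = (),
) -> CurationReport:
    """Screen ungapped candidate sequences; rejections are data, not errors.

    Rules are applied in the fixed order R1, R2, R3, R4, R5 per record,
    then R6 (duplicate removal, first kept) over the survivors, so the
    report is deterministic and ``curate`` is idempotent on its kept set.
    """
    metadata = metadata or {}
    exclude = frozenset(exclude_ids)
    rejected: list[tuple[str, str, str]] = []
    survivors: list[SequenceRecord] = []
    for rec in records:
        meta = metadata.get(rec.id, RecordMetadata())
        seq = rec.residues
        if rec.id in exclude:
            rejected.append((rec.id, "R1", "on explicit exclude list"))
        elif not _passes_cysteine_motif(seq, motif):
            rejected.append(
                (rec.id, "R2", f"cysteine cluster motif {motif!r} not satisfied")
            )
        elif meta.is_fragment:
            rejected.append((rec.id, "R3", "annotated as fragment"))
        elif not meta.has_signal_annotation:
            rejected.append((rec.id, "R4", "no annotated signal peptide"))
        elif meta.is_precursor and not seq.startswith("M"):
            rejected.append(
                (rec.id, "R4", "precursor does not start with methionine")
            )
        elif "X" in seq:
            rejected.append((rec.id, "R5", "contains unknown residue X"))
        else:
            survivors.append(rec)
    seen: set[tuple[str, str]] = set()
    kept: list[str] = []
    for rec in survivors:
        meta = metadata.get(rec.id, RecordMetadata())
        key = (rec.mnemonic, meta.gene)
        if key in seen:
            rejected.append(
                (rec.id, "R6", f"duplicate gene product for species {rec.mnemonic!r}")
            )
        else:
            seen.add(key)
            kept.append(rec.id)
    return CurationReport(kept=tuple(kept), rejected=tuple(rejected))
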
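"""Mapping between alignment/logo columns and reference residue numbers.

Alignments here carry mature sequences (signal peptides removed), while
published site tables number residues on the precursor, starting at the
initiator methionine. Mapping a region position to a precursor residue
therefore counts the reference row's non-gap characters from the start of
the alignment up to and including the mapped column, then adds the
reference's signal-peptide length. A position where the reference row has
a gap maps to ``None`` — a legitimate outcome (a site conserved in the
clade can be absent from the chosen reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .msa_io import GAP, SequenceRecord
from .regions import RegionSlice


@dataclass(frozen=True)
class ReferenceSpec:
    """Reference sequence and precursor offset for one protein family."""

    family: str
    reference_id: str
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        if self.signal_peptide_length < 0:
            raise ValueError("signal_peptide_length must be >= 0")


def _reference_row(region: RegionSlice, reference: ReferenceSpec) -> SequenceRecord:
    for rec in region.parent.records:
        if rec.id == reference.reference_id or (
            rec.accession and rec.accession == reference.reference_id
        ):
            return rec
    raise KeyError(
        f"reference id {reference.reference_id!r} not found in alignment"
    )


def column_to_residue(
    region: RegionSlice, reference: ReferenceSpec, position: int
) -> tuple[int | None, str | None]:
    """Precursor residue number (and identity) at a 1-based region position.

    Returns ``(None, None)`` when the reference row is gapped at the
    mapped column.
    """
    rec = _reference_row(region, reference)
    col = region.parent_column(position)  # 1-based parent column
    prefix = rec.residues[:col]
    if prefix[-1] == GAP:
        return None, None
    mature_index = len(prefix) - prefix.count(GAP)
    return mature_index + reference.signal_peptide_length, prefix[-1]


def residue_to_column(
    region: RegionSlice, reference: ReferenceSpec, residue_number: int
) -> int | None:
    """Inverse of :func:`column_to_residue` (region position or ``None``).

    ``residue_number`` is in precursor numbering and must lie beyond the
    signal peptide; residues past the reference's mature length or whose
    column falls outside the region map to ``None``.
    """
    if residue_number <= reference.signal_peptide_length:
        raise ValueError(
            f"residue {residue_number} lies inside the signal peptide "
            f"(length {reference.signal_peptide_length})"
        )
    rec = _reference_row(region, reference)
    target = residue_number - reference.signal_peptide_length
    seen = 0
    for col0, ch in enumerate(rec.residues):
        if ch != GAP:
            seen += 1
            if seen == target:
                col = col0 + 1
                if region.start <= col <= region.stop:
                    return col - region.start + 1
                return None
    return None


def mapping_table(region: RegionSlice, reference: ReferenceSpec) -> pd.DataFrame:
    """Region position ↔ reference residue table for the whole region."""
    rows = []
    for pos in range(1, region.n_columns + 1):
        number, identity = column_to_residue(region, reference, pos)
        rows.append(
            {
                "region_position": pos,
                "msa_column": region.parent_column(pos),
                "ref_residue_number": number if number is not None else "",
                "ref_residue": identity or "",
            }
        )
    return pd.DataFrame(rows)


def write_mapping_tsv(
    region: RegionSlice, reference: ReferenceSpec, path: str | Path
) -> Path:
    path = Path(path)
    mapping_table(region, reference).to_csv(path, sep="\t", index=False)
    return path
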
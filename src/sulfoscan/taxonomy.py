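"""Taxonomic class assignment and nested clade subsetting of alignments.

Each sequence is assigned to one of six jawed-vertebrate classes
(cartilaginous fish, ray-finned fish, lobe-finned fish, amphibians,
reptiles+birds, mammals) either from an explicit two-column table or from
a shipped organism-mnemonic map. Named clades are fixed unions of those
classes and nest strictly:

    amniotes ⊂ tetrapods ⊂ sarcopterygians ⊂ bony_vertebrates ⊂ jawed_vertebrates

Subsetting an alignment to a clade keeps only records of member classes,
drops columns that are gaps in every kept record, and returns a column
map back to the original alignment so positions remain diagnosable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .msa_io import GAP, Alignment

logger = logging.getLogger(__name__)

#: Closed vocabulary of taxonomic class labels.
CLASS_LABELS: tuple[str, ...] = (
    "cartilaginous_fish",
    "ray_finned_fish",
    "lobe_finned_fish",
    "amphibian",
    "reptile_bird",
    "mammal",
    "unassigned",
)

_ALL = frozenset(CLASS_LABELS) - {"unassigned"}

#: Named clade → member class labels (strictly nested).
CLADE_HIERARCHY: dict[str, frozenset[str]] = {
    "jawed_vertebrates": _ALL,
    "bony_vertebrates": _ALL - {"cartilaginous_fish"},
    "sarcopterygians": frozenset(
        {"lobe_finned_fish", "amphibian", "reptile_bird", "mammal"}
    ),
    "tetrapods": frozenset({"amphibian", "reptile_bird", "mammal"}),
    "amniotes": frozenset({"reptile_bird", "mammal"}),
}


class CladeError(ValueError):
    """Bad clade table or an empty clade subset."""


@dataclass(frozen=True)
class CladeTable:
    """Map from sequence id to taxonomic class label."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.assignments.values()} - set(CLASS_LABELS)
        if bad:
            raise CladeError(
                f"unknown class label(s) {sorted(bad)}; allowed: {list(CLASS_LABELS)}"
            )

    def label(self, record_id: str) -> str:
        return self.assignments.get(record_id, "unassigned")

    def counts(self) -> dict[str, int]:
        out = {lbl: 0 for lbl in CLASS_LABELS}
        for v in self.assignments.values():
            out[v] += 1
        return out


def load_clade_table(path: str | Path, alignment: Alignment) -> CladeTable:
    """Read a ``sequence_id<TAB>class_label`` table for an alignment.

    Ids present in the alignment but absent from the table are assigned
    ``unassigned`` with a logged warning; duplicate id rows and unknown
    labels are errors.
    """
    path = Path(path)
    assignments: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise CladeError(f"{path}: malformed row {row!r}")
            seq_id, label = row[0].strip(), row[1].strip()
            if seq_id in assignments:
                raise CladeError(f"{path}: duplicate id {seq_id!r}")
            if label not in CLASS_LABELS:
                raise CladeError(
                    f"{path}: unknown class label {label!r} for {seq_id!r}"
                )
            assignments[seq_id] = label
    missing = [rid for rid in alignment.ids if rid not in assignments]
    if missing:
        logger.warning(
            "%d alignment record(s) not in clade table, set to unassigned: %s",
            len(missing),
            ", ".join(missing[:5]) + ("..." if len(missing) > 5 else ""),
        )
    for rid in missing:
        assignments[rid] = "unassigned"
    return CladeTable(assignments)


def builtin_mnemonic_map() -> dict[str, str]:
    """The shipped organism-mnemonic → class table."""
    text = (
        resources.files("sulfoscan").joinpath("data/mnemonic_classes.tsv").read_text()
    )
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        mnem, label = line.split("\t")
        out[mnem] = label
    return out


def infer_from_mnemonics(
    alignment: Alignment, builtin_map: Mapping[str, str] | None = None
) -> CladeTable:
    """Assign classes from UniProt organism mnemonics (e.g. ``HUMAN``).

    Records whose mnemonic is missing from the map become ``unassigned``,
    with a single warning listing the unmapped mnemonics.
    """
    mapping = dict(builtin_map) if builtin_map is not None else builtin_mnemonic_map()
    assignments: dict[str, str] = {}
    unmapped: set[str] = set()
    for rec in alignment.records:
        label = mapping.get(rec.mnemonic)
        if label is None:
            unmapped.add(rec.mnemonic or "<none>")
            label = "unassigned"
        assignments[rec.id] = label
    if unmapped:
        logger.warning("unmapped organism mnemonics: %s", ", ".join(sorted(unmapped)))
    return CladeTable(assignments)


def subset_by_clade(
    alignment: Alignment, clade_table: CladeTable, clade_name: str
) -> tuple[Alignment, np.ndarray]:
    """Restrict an alignment to the records of a named clade.

    Unassigned records are always excluded. Columns that are gaps in every
    kept record are dropped. Returns the subset alignment and a strictly
    increasing ``column_map`` array: ``column_map[new_col_0based]`` is the
    1-based column index in the input alignment.
    """
    if clade_name not in CLADE_HIERARCHY:
        raise CladeError(
            f"unknown clade {clade_name!r}; known: {sorted(CLADE_HIERARCHY)}"
        )
    members = CLADE_HIERARCHY[clade_name]
    keep = [
        i
        for i, rec in enumerate(alignment.records)
        if clade_table.label(rec.id) in members
    ]
    if not keep:
        raise CladeError(
            f"clade {clade_name!r} selects no records; class counts: "
            f"{clade_table.counts()}"
        )
    sub = alignment.take_records(keep)
    mat = sub.matrix()
    nongap_cols = np.flatnonzero((mat != GAP).any(axis=0))
    column_map = nongap_cols + 1  # 1-based original columns
    return sub.take_columns(nongap_cols.tolist()), column_map
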
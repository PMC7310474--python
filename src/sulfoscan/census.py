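"""Terminal-region composition statistics per sequence and per clade.

For each sequence's region row the census records the ungapped length,
counts of the residues that characterise these terminal regions
(tyrosine; proline; the basic residues R and K; the acidic residues D and
E), and the identity of the first mature residue — an N-terminal
glutamine is biologically notable because it cyclises to pyroglutamate
and protects the mature protein from aminopeptidase trimming.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .conservation import round_half_up_percent
from .msa_io import GAP, AMINO_ACIDS
from .regions import RegionSlice
from .taxonomy import CladeTable

_COUNTED = "YPRKDE"


def census(region: RegionSlice, clade_table: CladeTable | None = None) -> pd.DataFrame:
    """One row per sequence: region length, residue counts, first residue."""
    rows = []
    for rec in region.sub.records:
        ungapped = rec.residues.replace(GAP, "")
        first = ungapped[0] if ungapped else ""
        row = {
            "id": rec.id,
            "clade_class": clade_table.label(rec.id) if clade_table else "unassigned",
            "region": region.kind,
            "length": len(ungapped),
            "first_residue": first,
            "first_residue_is_Q": first == "Q",
        }
        for aa in _COUNTED:
            row[f"n_{aa}"] = ungapped.count(aa)
        rows.append(row)
    return pd.DataFrame(rows)


def first_residue_frequency(region: RegionSlice, residue: str) -> int:
    """Percent of sequences whose first non-gap region character is ``residue``.

    Sequences whose region row is entirely gaps count against the
    frequency (all-sequence denominator, half-up rounding).
    """
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not one of the 20 amino acids")
    hits = 0
    for rec in region.sub.records:
        ungapped = rec.residues.replace(GAP, "")
        if ungapped and ungapped[0] == residue:
            hits += 1
    return round_half_up_percent(hits, region.sub.n_records)


def clade_summary(census_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-clade min/max region length and tyrosine count (supplementary-table style)."""
    grouped = census_frame.groupby(["clade_class", "region"], sort=True)
    out = grouped.agg(
        n_sequences=("id", "size"),
        min_length=("length", "min"),
        max_length=("length", "max"),
        min_Y=("n_Y", "min"),
        max_Y=("n_Y", "max"),
        q_start_fraction=("first_residue_is_Q", "mean"),
    ).reset_index()
    out["q_start_fraction"] = out["q_start_fraction"].round(4)
    return out


def write_census_tsv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path
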
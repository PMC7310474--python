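"""Cysteine anchor detection and terminal-region extraction.

The leucine-rich repeat core of these protein families is bounded by
conserved cysteines. The N-terminal region runs from the first mature
residue (alignment column 1, signal peptides having been removed) to the
column before the first anchor cysteine; the C-terminal region runs from
the column after the last anchor cysteine to the end of the alignment.
Anchor columns are those where the cysteine fraction among non-gap
residues reaches a threshold (default 0.9) and occupancy is at least 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa_io import GAP, Alignment


class RegionError(ValueError):
    """No qualifying anchor column, or an empty terminal region."""


@dataclass(frozen=True)
class RegionSlice:
    """A contiguous column window of an alignment.

    ``start``/``stop`` are 1-based inclusive column bounds in the parent
    alignment; ``column_map[i]`` is the 1-based parent column of region
    position ``i + 1``. Region positions are numbered from 1, matching
    sequence-logo numbering for N-terminal regions.
    """

    parent: Alignment
    kind: str  # "n_terminal" | "c_terminal"
    start: int
    stop: int
    sub: Alignment

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.stop <= self.parent.n_columns:
            raise RegionError(
                f"invalid region bounds {self.start}..{self.stop} "
                f"for alignment of {self.parent.n_columns} columns"
            )

    @property
    def n_columns(self) -> int:
        return self.stop - self.start + 1

    @property
    def column_map(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)

    def parent_column(self, position: int) -> int:
        """1-based parent column of a 1-based region position."""
        if not 1 <= position <= self.n_columns:
            raise RegionError(f"position {position} outside region 1..{self.n_columns}")
        return self.start + position - 1

    @classmethod
    def from_span(
        cls, parent: Alignment, kind: str, start: int, stop: int
    ) -> "RegionSlice":
        sub = parent.take_columns(range(start - 1, stop))
        return cls(parent=parent, kind=kind, start=start, stop=stop, sub=sub)


def find_anchor_cysteines(
    alignment: Alignment, min_c_fraction: float = 0.9
) -> list[int]:
    """Columns (1-based) qualifying as conserved cysteine anchors.

    A column qualifies when the fraction of its non-gap residues equal to
    ``C`` is at least ``min_c_fraction`` and its occupancy is at least
    0.5. ``min_c_fraction`` must lie in (0.5, 1].
    """
    if not 0.5 < min_c_fraction <= 1.0:
        raise ValueError("min_c_fraction must be in (0.5, 1]")
    mat = alignment.matrix()
    nongap = mat != GAP
    n_nongap = nongap.sum(axis=0)
    n_cys = (mat == "C").sum(axis=0)
    occupancy = n_nongap / alignment.n_records
    with np.errstate(invalid="ignore", divide="ignore"):
        c_fraction = np.where(n_nongap > 0, n_cys / np.maximum(n_nongap, 1), 0.0)
    cols = np.flatnonzero((c_fraction >= min_c_fraction) & (occupancy >= 0.5)) + 1
    if cols.size == 0:
        raise RegionError(
            f"no column reaches cysteine fraction {min_c_fraction} at occupancy "
            f">= 0.5; best column has fraction {float(c_fraction.max()):.2f} — "
            "consider lowering min_c_fraction"
        )
    return cols.tolist()


def n_terminal_region(alignment: Alignment, anchors: Sequence[int]) -> RegionSlice:
    """Columns 1 .. first_anchor − 1 (the variable N-terminal region)."""
    if not anchors:
        raise RegionError("anchor list is empty")
    first = min(anchors)
    if first <= 1:
        raise RegionError("first anchor at column 1: N-terminal region is empty")
    return RegionSlice.from_span(alignment, "n_terminal", 1, first - 1)


def c_terminal_region(alignment: Alignment, anchors: Sequence[int]) -> RegionSlice:
    """Columns last_anchor + 1 .. n_columns (the variable C-terminal region)."""
    if not anchors:
        raise RegionError("anchor list is empty")
    last = max(anchors)
    if last >= alignment.n_columns:
        raise RegionError(
            "last anchor at final column: C-terminal region is empty"
        )
    return RegionSlice.from_span(
        alignment, "c_terminal", last + 1, alignment.n_columns
    )


def export_region(region: RegionSlice, fasta_path: str | Path, map_path: str | Path):
    """Write the region as gapped FASTA plus a sidecar TSV of the column map."""
    from .msa_io import write_alignment

    write_alignment(region.sub, fasta_path)
    with open(map_path, "w") as fh:
        fh.write("region_position\tparent_column\n")
        for i, col in enumerate(region.column_map, start=1):
            fh.write(f"{i}\t{col}\n")
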
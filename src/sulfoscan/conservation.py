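"""Per-column residue statistics, residue classes, and logo matrices.

Residues are grouped into six classes by their effect on tyrosine
sulfation of a nearby tyrosine: tyrosine itself, acidic (E, D),
turn-inducing (P, G, N, S), basic/hydrophobic (R, K, H, F, W, I, M, V,
L), cysteine, and neutral (Q, A, T). The six classes partition the 20
amino acids exactly.

Conservation percentages are integers, rounded half-up, and are computed
with either all subset sequences in the denominator (gaps count against
conservation — the default, which reproduces figure-legend style values
such as 62/63 → 98) or non-gap sequences only.

Logo letter heights use the equiprobable-background information content
R = log2(20) − H, with H the Shannon entropy of the non-gap residue
frequencies; heights are p·R. No small-sample correction is applied by
default (a toggle is provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .msa_io import AMINO_ACIDS, GAP, Alignment
from .regions import RegionSlice


class ResidueClass(str, Enum):
    TYR = "TYR"
    ACIDIC = "ACIDIC"
    TURN = "TURN"
    BASIC_HYDROPHOBIC = "BASIC_HYDROPHOBIC"
    CYS = "CYS"
    NEUTRAL = "NEUTRAL"
    GAP = "GAP"


_CLASS_MEMBERS: dict[ResidueClass, str] = {
    ResidueClass.TYR: "Y",
    ResidueClass.ACIDIC: "ED",
    ResidueClass.TURN: "PGNS",
    ResidueClass.BASIC_HYDROPHOBIC: "RKHFWIMVL",
    ResidueClass.CYS: "C",
    ResidueClass.NEUTRAL: "QAT",
}

#: residue → class; 'X' (unknown) is treated as NEUTRAL so it never counts
#: as promoting or suppressing.
RESIDUE_CLASS: dict[str, ResidueClass] = {
    aa: cls for cls, members in _CLASS_MEMBERS.items() for aa in members
}
RESIDUE_CLASS["X"] = ResidueClass.NEUTRAL
RESIDUE_CLASS[GAP] = ResidueClass.GAP


def residue_class(residue: str) -> ResidueClass:
    try:
        return RESIDUE_CLASS[residue]
    except KeyError:
        raise ValueError(f"unknown residue {residue!r}") from None


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """100·numerator/denominator rounded half-up to the nearest integer."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class ColumnProfile:
    """Residue tally of one region column (1-based ``position``)."""

    position: int
    counts: dict[str, int]  # non-gap residues only
    n_total: int
    occupancy: float
    consensus_residue: str | None  # None when the column is all gaps / all X
    consensus_tied: bool
    consensus_fraction_all: float
    consensus_fraction_nongap: float
    class_of_consensus: ResidueClass

    @property
    def n_nongap(self) -> int:
        return sum(self.counts.values())

    def count(self, residue: str) -> int:
        return self.counts.get(residue, 0)


def _profile_one(column: np.ndarray, position: int) -> ColumnProfile:
    n_total = column.size
    residues, tallies = np.unique(column[column != GAP], return_counts=True)
    counts = dict(zip(residues.tolist(), tallies.tolist()))
    n_nongap = sum(counts.values())
    occupancy = n_nongap / n_total
    # consensus over the 20 standard amino acids; ties broken alphabetically
    standard = {aa: c for aa, c in counts.items() if aa in AMINO_ACIDS}
    if standard:
        best = max(standard.values())
        winners = sorted(aa for aa, c in standard.items() if c == best)
        consensus = winners[0]
        tied = len(winners) > 1
        frac_all = standard[consensus] / n_total
        frac_nongap = standard[consensus] / n_nongap
        cls = RESIDUE_CLASS[consensus]
    else:
        consensus, tied, frac_all, frac_nongap = None, False, 0.0, 0.0
        cls = ResidueClass.GAP
    return ColumnProfile(
        position=position,
        counts=counts,
        n_total=n_total,
        occupancy=occupancy,
        consensus_residue=consensus,
        consensus_tied=tied,
        consensus_fraction_all=frac_all,
        consensus_fraction_nongap=frac_nongap,
        class_of_consensus=cls,
    )


def _as_alignment(region: Union[RegionSlice, Alignment]) -> Alignment:
    return region.sub if isinstance(region, RegionSlice) else region


def profile_columns(region: Union[RegionSlice, Alignment]) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column, positions numbered from 1."""
    aln = _as_alignment(region)
    mat = aln.matrix()
    return [_profile_one(mat[:, j], j + 1) for j in range(aln.n_columns)]


def conservation_percent(
    profile: ColumnProfile, residue: str, denominator: str = "all"
) -> int:
    """Integer conservation percent of ``residue`` at this column.

    ``denominator="all"`` counts gaps against conservation (default);
    ``"nongap"`` restricts to occupied rows.
    """
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not one of the 20 amino acids")
    if denominator == "all":
        denom = profile.n_total
    elif denominator == "nongap":
        denom = profile.n_nongap
    else:
        raise ValueError("denominator must be 'all' or 'nongap'")
    return round_half_up_percent(profile.count(residue), denom)


MAX_INFORMATION_BITS = math.log2(20.0)


def information_content(
    profile: ColumnProfile, small_sample_correction: bool = False
) -> float:
    """Column information content R = log2(20) − H in bits (0 if all-gap)."""
    freqs = _nongap_frequencies(profile)
    if freqs.size == 0:
        return 0.0
    entropy = float(-(freqs * np.log2(freqs)).sum())
    correction = 0.0
    if small_sample_correction and profile.n_nongap > 0:
        correction = (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * profile.n_nongap)
    return max(0.0, MAX_INFORMATION_BITS - entropy - correction)


def _nongap_frequencies(profile: ColumnProfile) -> np.ndarray:
    standard = [profile.count(aa) for aa in AMINO_ACIDS]
    total = sum(standard)
    if total == 0:
        return np.array([])
    arr = np.array(standard, dtype=float) / total
    return arr[arr > 0]


def logo_matrix(
    region: Union[RegionSlice, Alignment], small_sample_correction: bool = False
) -> pd.DataFrame:
    """Per-column letter heights (frequency × information content).

    Returns a DataFrame indexed by 1-based position with one column per
    amino acid; row sums equal the column information content. All-gap
    columns have height 0 everywhere.
    """
    profiles = profile_columns(region)
    heights = np.zeros((len(profiles), len(AMINO_ACIDS)))
    for i, prof in enumerate(profiles):
        ic = information_content(prof, small_sample_correction)
        n_nongap = sum(prof.count(aa) for aa in AMINO_ACIDS)
        if n_nongap == 0:
            continue
        for j, aa in enumerate(AMINO_ACIDS):
            heights[i, j] = ic * prof.count(aa) / n_nongap
    return pd.DataFrame(
        heights,
        index=pd.Index([p.position for p in profiles], name="position"),
        columns=list(AMINO_ACIDS),
    )


def profiles_to_frame(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """Tabular view of column profiles (one row per column)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "position": p.position,
                "n_total": p.n_total,
                "occupancy": round(p.occupancy, 4),
                "consensus": p.consensus_residue or "-",
                "consensus_tied": p.consensus_tied,
                "consensus_class": p.class_of_consensus.value,
                "consensus_percent_all": round_half_up_percent(
                    p.count(p.consensus_residue) if p.consensus_residue else 0,
                    p.n_total,
                ),
                "consensus_percent_nongap": round_half_up_percent(
                    p.count(p.consensus_residue) if p.consensus_residue else 0,
                    p.n_nongap,
                ),
                "tyr_percent_all": conservation_percent(p, "Y", "all"),
                "tyr_percent_nongap": conservation_percent(p, "Y", "nongap"),
            }
        )
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: Sequence[ColumnProfile], path: str | Path) -> Path:
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
    return path


def write_logo_tsv(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path, sep="\t")
    return path
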
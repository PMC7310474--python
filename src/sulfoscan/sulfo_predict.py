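"""Three cut-off rules for predicting sulfation-prone tyrosine columns.

A tyrosine column in a terminal-region alignment is predicted as a
sulfation site when all three rules pass:

C1  conservation — at least 75% of the subset sequences carry a tyrosine
    at the column (gaps count against, integer percent, half-up);
C2  context — among the columns within ±5 positions of the tyrosine, the
    ratio of sulfation-promoting to (promoting + suppressing) consensus
    residues is at least 0.5. Each context column contributes through the
    class of its consensus residue (the tallest logo letter). Neutral
    (Q/A/T) columns are excluded from the ratio by default, and tyrosine
    counts as promoting (tyrosines cluster at sulfation sites);
C3  occupancy — the tyrosine column is occupied (non-gap) in at least 50%
    of sequences. Context columns below the occupancy floor are likewise
    excluded from the C2 window.

Every threshold and class assignment is a field of
:class:`PredictionRule`, so each reading of the rules is a configuration
switch, not a code change. Auxiliary flags (a consensus cysteine within
±7, an N-glycosylation sequon N-x-S/T with x≠P in the consensus context)
are advisory only and never change the prediction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .conservation import (
    ColumnProfile,
    ResidueClass,
    conservation_percent,
    profile_columns,
)
from .msa_io import Alignment
from .regions import RegionSlice

PROMOTING_DEFAULT = frozenset(
    {ResidueClass.TYR, ResidueClass.ACIDIC, ResidueClass.TURN}
)
SUPPRESSING_DEFAULT = frozenset({ResidueClass.BASIC_HYDROPHOBIC, ResidueClass.CYS})


@dataclass(frozen=True)
class PredictionRule:
    """Thresholds and class sets for the three cut-off rules."""

    c1_min_y_percent: int = 75
    c2_min_promoting_ratio: float = 0.5
    c2_window: int = 5
    c3_min_occupancy: float = 0.5
    promoting_classes: frozenset[ResidueClass] = PROMOTING_DEFAULT
    suppressing_classes: frozenset[ResidueClass] = SUPPRESSING_DEFAULT
    neutral_excluded: bool = True
    aux_window: int = 7

    def __post_init__(self) -> None:
        if self.promoting_classes & self.suppressing_classes:
            raise ValueError("promoting and suppressing classes overlap")
        if not 0 <= self.c1_min_y_percent <= 100:
            raise ValueError("c1_min_y_percent must be in [0, 100]")
        if not 0.0 <= self.c2_min_promoting_ratio <= 1.0:
            raise ValueError("c2_min_promoting_ratio must be in [0, 1]")
        if not 0.0 <= self.c3_min_occupancy <= 1.0:
            raise ValueError("c3_min_occupancy must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["promoting_classes"] = sorted(c.value for c in self.promoting_classes)
        d["suppressing_classes"] = sorted(c.value for c in self.suppressing_classes)
        return d


@dataclass
class PredictionRecord:
    """Rule-by-rule diagnostics for one candidate tyrosine column."""

    position: int  # 1-based region position
    msa_column: int  # 1-based column in the (subset) alignment
    y_percent: int
    occupancy: float
    window_used: tuple[int, ...]
    n_promoting: int
    n_suppressing: int
    promoting_ratio: float | None  # None when both counts are zero
    c1: bool
    c2: bool
    c3: bool
    indeterminate_context: bool
    predicted: bool
    cys_within_7: bool
    nglyc_motif_within_window: bool
    ref_residue_number: int | None = None
    ref_residue: str | None = None


def candidate_columns(
    profiles: Sequence[ColumnProfile], rule: PredictionRule | None = None
) -> list[int]:
    """Positions passing cut-off C1 (tyrosine conservation)."""
    rule = rule or PredictionRule()
    return [
        p.position
        for p in profiles
        if conservation_percent(p, "Y", "all") >= rule.c1_min_y_percent
    ]


def context_ratio(
    profiles: Sequence[ColumnProfile],
    position: int,
    rule: PredictionRule | None = None,
) -> tuple[int, int, float | None, tuple[int, ...]]:
    """Promoting/suppressing tally over the ±window context of a column.

    The tyrosine's own column never contributes. Columns outside the
    region, below the occupancy floor, all-gap, or (by default) with a
    neutral-class consensus are excluded. Returns
    ``(n_promoting, n_suppressing, ratio, window_used)`` with ``ratio``
    ``None`` when both counts are zero (indeterminate context).
    """
    rule = rule or PredictionRule()
    by_pos = {p.position: p for p in profiles}
    if position not in by_pos:
        raise ValueError(f"position {position} not in profiles")
    window_used: list[int] = []
    n_promoting = n_suppressing = 0
    for offset in range(-rule.c2_window, rule.c2_window + 1):
        if offset == 0:
            continue
        prof = by_pos.get(position + offset)
        if prof is None or prof.occupancy < rule.c3_min_occupancy:
            continue
        cls = prof.class_of_consensus
        if cls is ResidueClass.GAP:
            continue
        if cls in rule.promoting_classes:
            n_promoting += 1
            window_used.append(prof.position)
        elif cls in rule.suppressing_classes:
            n_suppressing += 1
            window_used.append(prof.position)
        elif not rule.neutral_excluded:
            # neutral columns count in the denominator when not excluded
            n_suppressing += 0
            window_used.append(prof.position)
    denom = n_promoting + n_suppressing
    if not rule.neutral_excluded:
        denom = len(window_used)
    ratio = n_promoting / denom if denom else None
    return n_promoting, n_suppressing, ratio, tuple(window_used)


def aux_feature_flags(
    profiles: Sequence[ColumnProfile], position: int, window: int = 7
) -> tuple[bool, bool]:
    """Advisory flags over the ±``window`` consensus context.

    ``cys_within_7``: any context column (excluding the tyrosine itself)
    has consensus cysteine. ``nglyc_motif_within_window``: the consensus
    string over the window (including the tyrosine column) contains the
    sequon N-x-S/T with x ≠ P.
    """
    by_pos = {p.position: p for p in profiles}
    cys = False
    chars: list[str] = []
    for pos in range(position - window, position + window + 1):
        prof = by_pos.get(pos)
        if prof is None:
            continue
        chars.append(prof.consensus_residue or "-")
        if pos != position and prof.consensus_residue == "C":
            cys = True
    consensus = "".join(chars)
    nglyc = any(
        consensus[i] == "N"
        and consensus[i + 1] not in ("P", "-")
        and consensus[i + 2] in ("S", "T")
        for i in range(len(consensus) - 2)
    )
    return cys, nglyc


def predict(
    region: Union[RegionSlice, Alignment],
    rule: PredictionRule | None = None,
    profiles: Sequence[ColumnProfile] | None = None,
) -> list[PredictionRecord]:
    """Full diagnostic records for every C1 candidate in the region."""
    rule = rule or PredictionRule()
    if profiles is None:
        profiles = profile_columns(region)
    if len(profiles) < 2:
        raise ValueError("a region must have at least 2 columns to predict on")
    by_pos = {p.position: p for p in profiles}
    records: list[PredictionRecord] = []
    for pos in candidate_columns(profiles, rule):
        prof = by_pos[pos]
        n_pro, n_sup, ratio, window_used = context_ratio(profiles, pos, rule)
        indeterminate = ratio is None
        c1 = True
        c2 = indeterminate or ratio >= rule.c2_min_promoting_ratio
        c3 = prof.occupancy >= rule.c3_min_occupancy
        cys, nglyc = aux_feature_flags(profiles, pos, rule.aux_window)
        if isinstance(region, RegionSlice):
            msa_column = region.parent_column(pos)
        else:
            msa_column = pos
        records.append(
            PredictionRecord(
                position=pos,
                msa_column=msa_column,
                y_percent=conservation_percent(prof, "Y", "all"),
                occupancy=prof.occupancy,
                window_used=window_used,
                n_promoting=n_pro,
                n_suppressing=n_sup,
                promoting_ratio=ratio,
                c1=c1,
                c2=c2,
                c3=c3,
                indeterminate_context=indeterminate,
                predicted=c1 and c2 and c3,
                cys_within_7=cys,
                nglyc_motif_within_window=nglyc,
            )
        )
    return records


def predicted_positions(records: Sequence[PredictionRecord]) -> list[int]:
    return [r.position for r in records if r.predicted]


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "position": r.position,
            "msa_column": r.msa_column,
            "y_percent": r.y_percent,
            "occupancy": round(r.occupancy, 4),
            "n_promoting": r.n_promoting,
            "n_suppressing": r.n_suppressing,
            "promoting_ratio": (
                round(r.promoting_ratio, 4) if r.promoting_ratio is not None else ""
            ),
            "c1": r.c1,
            "c2": r.c2,
            "c3": r.c3,
            "indeterminate_context": r.indeterminate_context,
            "predicted": r.predicted,
            "cys_within_7": r.cys_within_7,
            "nglyc_motif_within_window": r.nglyc_motif_within_window,
            "ref_residue_number": (
                r.ref_residue_number if r.ref_residue_number is not None else ""
            ),
            "ref_residue": r.ref_residue or "",
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_predictions(
    records: Sequence[PredictionRecord],
    rule: PredictionRule,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Prediction report as TSV, plus a JSON variant embedding the rule."""
    records_to_frame(records).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "rule": rule.to_dict(),
            "records": [
                {
                    **{
                        k: v
                        for k, v in r.__dict__.items()
                        if k != "window_used"
                    },
                    "window_used": list(r.window_used),
                }
                for r in records
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
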
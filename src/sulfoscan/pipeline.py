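"""Orchestration: curation → clade subsetting → regions → profiles →
prediction → reference mapping → reports.

One :class:`RunConfig` describes one protein family: which alignment to
read, how to assign taxonomic classes, which clade to analyse, which
terminal regions to scan, and which reference sequence (with its
signal-peptide length) to map predictions onto. :func:`run_family`
executes the chain and writes TSV/JSON reports plus a manifest that
suffices to re-execute the run; :func:`run_all` aggregates families into
a cross-family summary (distinct mapped reference tyrosines, plus a
presence/absence matrix of terminal features per taxonomic class).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .census import census, clade_summary, first_residue_frequency, write_census_tsv
from .conservation import logo_matrix, profile_columns, write_logo_tsv, write_profiles_tsv
from .coord_map import ReferenceSpec, column_to_residue, write_mapping_tsv
from .msa_io import Alignment, read_alignment
from .regions import (
    RegionSlice,
    c_terminal_region,
    find_anchor_cysteines,
    n_terminal_region,
)
from .sulfo_predict import PredictionRule, PredictionRecord, predict, write_predictions
from .taxonomy import CladeTable, infer_from_mnemonics, load_clade_table, subset_by_clade

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to analyse one family (no hidden state)."""

    family: str
    alignment_path: str
    clade: str
    clade_table_path: str = "infer"  # "infer" → use organism mnemonics
    region_kinds: tuple[str, ...] = ("n_terminal",)
    reference: ReferenceSpec | None = None
    rule: PredictionRule = field(default_factory=PredictionRule)
    min_c_fraction: float = 0.9
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        ref = d.get("reference")
        reference = (
            ReferenceSpec(
                family=d["family"],
                reference_id=ref["id"],
                signal_peptide_length=int(ref.get("signal_peptide_length", 0)),
            )
            if ref
            else None
        )
        rule = PredictionRule(**d.get("rule", {}))
        return cls(
            family=d["family"],
            alignment_path=d["alignment"],
            clade=d["clade"],
            clade_table_path=d.get("clade_table", "infer"),
            region_kinds=tuple(d.get("regions", ["n_terminal"])),
            reference=reference,
            rule=rule,
            min_c_fraction=float(d.get("min_c_fraction", 0.9)),
            out_dir=d.get("out_dir", "results"),
        )


@dataclass
class FamilyResult:
    """In-memory outcome of one family run."""

    config: RunConfig
    subset: Alignment
    regions: dict[str, RegionSlice]
    predictions: dict[str, list[PredictionRecord]]
    census_frames: dict[str, pd.DataFrame]
    manifest: dict

    def predicted_reference_residues(self) -> list[int]:
        """Distinct mapped reference residue numbers that are tyrosines."""
        out = set()
        for records in self.predictions.values():
            for rec in records:
                if rec.predicted and rec.ref_residue == "Y":
                    out.add(rec.ref_residue_number)
        return sorted(out)

    def unmapped_predictions(self) -> list[tuple[str, int]]:
        """Predicted sites mapping to a gap or a non-Y reference residue."""
        out = []
        for kind, records in self.predictions.items():
            for rec in records:
                if rec.predicted and rec.ref_residue != "Y":
                    out.append((kind, rec.position))
        return out


def _load_clades(config: RunConfig, alignment: Alignment) -> CladeTable:
    if config.clade_table_path == "infer":
        return infer_from_mnemonics(alignment)
    return load_clade_table(config.clade_table_path, alignment)


def run_family(config: RunConfig, write: bool = True) -> FamilyResult:
    """Run the full analysis chain for one family.

    Anchors are located on the full alignment, then the alignment is
    subset to the analysis clade (all-gap columns dropped) and anchors
    are re-located on the subset; logo positions are numbered on the
    subset columns.
    """
    alignment = read_alignment(config.alignment_path)
    clade_table = _load_clades(config, alignment)
    subset, column_map = subset_by_clade(alignment, clade_table, config.clade)
    anchors = find_anchor_cysteines(subset, config.min_c_fraction)

    out = Path(config.out_dir) / config.family
    if write:
        out.mkdir(parents=True, exist_ok=True)

    regions: dict[str, RegionSlice] = {}
    predictions: dict[str, list[PredictionRecord]] = {}
    census_frames: dict[str, pd.DataFrame] = {}
    for kind in config.region_kinds:
        if kind == "n_terminal":
            region = n_terminal_region(subset, anchors)
        elif kind == "c_terminal":
            region = c_terminal_region(subset, anchors)
        else:
            raise ValueError(f"unknown region kind {kind!r}")
        regions[kind] = region
        profiles = profile_columns(region)
        records = predict(region, config.rule, profiles=profiles)
        if config.reference is not None:
            for rec in records:
                number, identity = column_to_residue(
                    region, config.reference, rec.position
                )
                rec.ref_residue_number = number
                rec.ref_residue = identity
        predictions[kind] = records
        census_frames[kind] = census(region, clade_table)
        if write:
            prefix = out / kind
            write_profiles_tsv(profiles, f"{prefix}_profiles.tsv")
            write_logo_tsv(logo_matrix(region), f"{prefix}_logo.tsv")
            write_predictions(
                records,
                config.rule,
                f"{prefix}_predictions.tsv",
                f"{prefix}_predictions.json",
            )
            write_census_tsv(census_frames[kind], f"{prefix}_census.tsv")
            if config.reference is not None:
                write_mapping_tsv(region, config.reference, f"{prefix}_mapping.tsv")

    manifest = {
        "sulfoscan_version": __version__,
        "family": config.family,
        "alignment": str(config.alignment_path),
        "clade": config.clade,
        "clade_table": config.clade_table_path,
        "n_records_total": alignment.n_records,
        "n_records_subset": subset.n_records,
        "anchors_subset_columns": anchors,
        "subset_column_map_span": [int(column_map[0]), int(column_map[-1])],
        "min_c_fraction": config.min_c_fraction,
        "rule": config.rule.to_dict(),
        "regions": list(config.region_kinds),
        "reference": (
            {
                "id": config.reference.reference_id,
                "signal_peptide_length": config.reference.signal_peptide_length,
            }
            if config.reference
            else None
        ),
    }
    if write:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "%s/%s: %d records, anchors at %s",
        config.family,
        config.clade,
        subset.n_records,
        anchors,
    )
    return FamilyResult(
        config=config,
        subset=subset,
        regions=regions,
        predictions=predictions,
        census_frames=census_frames,
        manifest=manifest,
    )


def _feature_matrix(results: Sequence[FamilyResult]) -> pd.DataFrame:
    """Presence/absence of a tyrosine-rich terminal region per class.

    A feature is called present in a taxonomic class when at least half
    of that class's sequences carry ≥ 2 tyrosines in the region.
    """
    rows = []
    for res in results:
        for kind, frame in res.census_frames.items():
            for cls, grp in frame.groupby("clade_class"):
                present = bool((grp["n_Y"] >= 2).mean() >= 0.5)
                rows.append(
                    {
                        "family": res.config.family,
                        "region": kind,
                        "clade_class": cls,
                        "n_sequences": len(grp),
                        "tyrosine_rich": present,
                    }
                )
    return pd.DataFrame(rows)


def run_all(
    configs: Sequence[RunConfig], write: bool = True, out_dir: str | None = None
) -> dict:
    """Run several families and aggregate a cross-family summary."""
    results: list[FamilyResult] = []
    failures: dict[str, str] = {}
    for cfg in configs:
        try:
            results.append(run_family(cfg, write=write))
        except Exception as exc:  # per-family failures reported, run continues
            logger.error("family %s failed: %s", cfg.family, exc)
            failures[cfg.family] = str(exc)
    per_family = {}
    total = 0
    for res in results:
        mapped = res.predicted_reference_residues()
        unmapped = res.unmapped_predictions()
        total += len(mapped)
        per_family[res.config.family] = {
            "clade": res.config.clade,
            "n_subset_records": res.subset.n_records,
            "predicted_positions": {
                kind: [r.position for r in recs if r.predicted]
                for kind, recs in res.predictions.items()
            },
            "mapped_reference_residues": mapped,
            "unmapped_predictions": [list(u) for u in unmapped],
        }
    summary = {
        "n_families": len(results),
        "total_mapped_reference_residues": total,
        "per_family": per_family,
        "failures": failures,
    }
    if write and results:
        out = Path(out_dir or results[0].config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        _feature_matrix(results).to_csv(
            out / "feature_matrix.tsv", sep="\t", index=False
        )
    return summary


def load_run_configs(path: str | Path) -> list[RunConfig]:
    """Read a YAML config file: ``families:`` list of RunConfig mappings."""
    doc = yaml.safe_load(Path(path).read_text())
    out_dir = doc.get("out_dir", "results")
    configs = []
    for entry in doc["families"]:
        entry.setdefault("out_dir", out_dir)
        configs.append(RunConfig.from_dict(entry))
    return configs
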
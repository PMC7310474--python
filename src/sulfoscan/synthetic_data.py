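"""Synthetic alignment families with planted sulfation-prone tyrosines.

The generator emulates the statistical structure the analysis assumes: a
family of mature aligned sequences with (i) fully conserved cysteine
anchor columns arranged as an N-terminal cluster plus C-terminal pair,
(ii) tyrosine columns planted in the terminal regions at controlled
conservation levels with context columns drawn from configurable
promoting/suppressing residue mixes, (iii) i.i.d. per-cell gaps at a
configurable rate (anchor and site columns kept gap-free so ground truth
stays interpretable), and (iv) optional clade-specific insertion blocks
that are all-gap in the other classes, emulating lineage-specific
terminal extensions.

Ground truth (realised per-site conservation and context composition,
clade labels, anchor columns) is emitted alongside every alignment so
each pipeline stage can be tested against what was actually generated,
not only against what was requested: at finite family sizes the realised
tyrosine fraction of a site jitters binomially around its configured
level, and recovery statistics are reported both marginally and
conditionally on the realised column (see :func:`recovery_experiment`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa_io import GAP, Alignment, SequenceRecord
from .regions import c_terminal_region, find_anchor_cysteines, n_terminal_region
from .sulfo_predict import PredictionRule, predict
from .taxonomy import CladeTable

#: Residues drawn for promoting context cells (acidic + turn-inducing;
#: Y is deliberately not in the pool so planted columns stay the only
#: strongly tyrosine-conserved ones).
PROMOTING_POOL = "EDPGNS"
#: Residues drawn for suppressing context cells (basic/hydrophobic).
SUPPRESSING_POOL = "RKHFWIMVL"
#: Background: uniform over the 19 non-cysteine amino acids (no accidental
#: anchor columns).
BACKGROUND_POOL = "ADEFGHIKLMNPQRSTVWY"
#: Off-draws at site columns exclude Y as well, so a site's realised
#: Bernoulli level equals its configured conservation.
SITE_OFF_POOL = BACKGROUND_POOL.replace("Y", "")

#: Cysteine cluster planted between the N region and the core
#: (C-xx-C-x-C-xxxxxxxx-C, inside the default curation motif spacings).
CLUSTER_TEMPLATE = "C..C.C........C"
#: Two conserved cysteines closing the core.
TAIL_TEMPLATE = "C...C"

_CLASS_ORDER = (
    "mammal",
    "reptile_bird",
    "amphibian",
    "lobe_finned_fish",
    "ray_finned_fish",
    "cartilaginous_fish",
)


class ConfigError(ValueError):
    """Infeasible synthetic-family configuration."""


@dataclass(frozen=True)
class PlantedSite:
    """A tyrosine column planted at a configured conservation level.

    ``position`` is the 1-based alignment column (default layout puts the
    N region first, so N-region positions coincide with region-relative
    logo positions). ``promoting_fraction`` is the per-cell probability
    that a context cell within ±5 columns is drawn from the promoting
    pool rather than the suppressing pool.
    """

    position: int
    conservation: float
    promoting_fraction: float = 0.8
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.conservation <= 1.0:
            raise ConfigError("conservation must be in [0, 1]")
        if not 0.0 <= self.promoting_fraction <= 1.0:
            raise ConfigError("promoting_fraction must be in [0, 1]")


@dataclass(frozen=True)
class InsertionBlock:
    """Columns present only in the given classes (all-gap elsewhere)."""

    classes: frozenset[str]
    start: int
    stop: int


@dataclass(frozen=True)
class FamilyConfig:
    """Layout and statistical parameters of one synthetic family.

    Columns are laid out as: N region (``n_region_length`` columns),
    cysteine cluster, core, C-terminal cysteine pair, C region.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "mammal": 20,
            "reptile_bird": 10,
            "amphibian": 10,
            "ray_finned_fish": 15,
            "cartilaginous_fish": 5,
        }
    )
    n_region_length: int = 70
    core_length: int = 30
    c_region_length: int = 40
    planted_sites: tuple[PlantedSite, ...] = (
        PlantedSite(10, 0.95),
        PlantedSite(25, 0.85),
        PlantedSite(40, 0.80),
    )
    decoy_sites: tuple[PlantedSite, ...] = (
        PlantedSite(53, 0.50, promoting_fraction=0.8, is_decoy=True),
        PlantedSite(65, 0.90, promoting_fraction=0.0, is_decoy=True),
    )
    gap_rate: float = 0.05
    insertion_blocks: tuple[InsertionBlock, ...] = ()
    seed: int = 17

    @property
    def n_sequences(self) -> int:
        return sum(self.n_per_class.values())

    @property
    def cluster_start(self) -> int:
        return self.n_region_length + 1

    @property
    def anchor_columns(self) -> tuple[int, ...]:
        offset_cluster = self.n_region_length
        cluster = tuple(
            offset_cluster + i + 1
            for i, ch in enumerate(CLUSTER_TEMPLATE)
            if ch == "C"
        )
        offset_tail = self.n_region_length + len(CLUSTER_TEMPLATE) + self.core_length
        tail = tuple(
            offset_tail + i + 1 for i, ch in enumerate(TAIL_TEMPLATE) if ch == "C"
        )
        return cluster + tail

    @property
    def n_columns(self) -> int:
        return (
            self.n_region_length
            + len(CLUSTER_TEMPLATE)
            + self.core_length
            + len(TAIL_TEMPLATE)
            + self.c_region_length
        )

    @property
    def c_region_start(self) -> int:
        return self.n_columns - self.c_region_length + 1

    def all_sites(self) -> tuple[PlantedSite, ...]:
        return self.planted_sites + self.decoy_sites

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise ConfigError("at least one sequence required")
        unknown = set(self.n_per_class) - set(_CLASS_ORDER)
        if unknown:
            raise ConfigError(f"unknown class labels {sorted(unknown)}")
        positions = [s.position for s in self.all_sites()]
        if len(set(positions)) != len(positions):
            raise ConfigError("planted and decoy positions must be disjoint")
        n_lo, n_hi = 1, self.n_region_length
        c_lo, c_hi = self.c_region_start, self.n_columns
        for site in self.all_sites():
            p = site.position
            if n_lo <= p <= n_hi:
                lo, hi = n_lo, n_hi
            elif c_lo <= p <= c_hi:
                lo, hi = c_lo, c_hi
            else:
                raise ConfigError(
                    f"site column {p} is not inside the N ({n_lo}..{n_hi}) or "
                    f"C ({c_lo}..{c_hi}) region"
                )
            if p - lo < 5 or hi - p < 5:
                raise ConfigError(
                    f"site column {p} is closer than 6 columns to a region edge "
                    "(its ±5 context window would be truncated)"
                )
        for block in self.insertion_blocks:
            if not 1 <= block.start <= block.stop <= self.n_columns:
                raise ConfigError(f"insertion block {block} out of bounds")


@dataclass(frozen=True)
class SiteTruth:
    position: int
    configured_conservation: float
    realised_y_fraction: float
    realised_promoting_fraction: float
    occupancy: float
    is_decoy: bool


@dataclass(frozen=True)
class SyntheticTruth:
    sites: tuple[SiteTruth, ...]
    anchor_columns: tuple[int, ...]
    clade_of: dict[str, str]

    @property
    def planted(self) -> tuple[SiteTruth, ...]:
        return tuple(s for s in self.sites if not s.is_decoy)

    @property
    def decoys(self) -> tuple[SiteTruth, ...]:
        return tuple(s for s in self.sites if s.is_decoy)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "anchor_columns": list(self.anchor_columns),
            "clade_of": self.clade_of,
            "sites": [s.__dict__ for s in self.sites],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _draw(rng: np.random.Generator, pool: str, shape) -> np.ndarray:
    letters = np.array(list(pool), dtype="<U1")
    return letters[rng.integers(0, len(letters), size=shape)]


def generate_family(
    config: FamilyConfig | None = None,
) -> tuple[Alignment, CladeTable, SyntheticTruth]:
    """Generate one family: alignment, clade labels, and ground truth.

    Deterministic for a fixed config (including its seed): identical
    inputs give byte-identical FASTA output.
    """
    config = config or FamilyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_cols = config.n_sequences, config.n_columns

    mat = _draw(rng, BACKGROUND_POOL, (n, n_cols))

    # cysteine anchors: 100% conserved
    for col in config.anchor_columns:
        mat[:, col - 1] = "C"

    # context columns first, then site columns (sites win any overlap)
    site_cols = {s.position for s in config.all_sites()}
    anchor_cols = set(config.anchor_columns)
    context_cells: dict[int, np.ndarray] = {}
    for site in config.all_sites():
        for col in range(site.position - 5, site.position + 6):
            if col == site.position or col < 1 or col > n_cols:
                continue
            if col in site_cols or col in anchor_cols:
                continue
            promoting = rng.random(n) < site.promoting_fraction
            cells = np.where(
                promoting,
                _draw(rng, PROMOTING_POOL, n),
                _draw(rng, SUPPRESSING_POOL, n),
            )
            mat[:, col - 1] = cells
            context_cells[col] = promoting
    for site in config.all_sites():
        hit = rng.random(n) < site.conservation
        mat[:, site.position - 1] = np.where(hit, "Y", _draw(rng, SITE_OFF_POOL, n))

    # class labels in fixed order, then clade-specific insertion blocks
    labels: list[str] = []
    for cls in _CLASS_ORDER:
        labels.extend([cls] * config.n_per_class.get(cls, 0))
    label_arr = np.array(labels)
    for block in config.insertion_blocks:
        outside = ~np.isin(label_arr, list(block.classes))
        mat[np.ix_(outside, np.arange(block.start - 1, block.stop))] = GAP

    # i.i.d. gaps everywhere except anchor and site columns
    protected = np.zeros(n_cols, dtype=bool)
    for col in anchor_cols | site_cols:
        protected[col - 1] = True
    if config.gap_rate > 0:
        gap_mask = rng.random((n, n_cols)) < config.gap_rate
        gap_mask[:, protected] = False
        mat[gap_mask] = GAP

    records = tuple(
        SequenceRecord(
            id=f"syn{i:04d}_{labels[i]}",
            residues="".join(mat[i]),
        )
        for i in range(n)
    )
    alignment = Alignment(records)
    clade_table = CladeTable({rec.id: labels[i] for i, rec in enumerate(records)})

    site_truths = []
    for site in config.all_sites():
        col = mat[:, site.position - 1]
        nongap = col != GAP
        y_fraction = float((col == "Y").mean())
        promo = [
            context_cells[c]
            for c in range(site.position - 5, site.position + 6)
            if c in context_cells
        ]
        promoting_fraction = (
            float(np.concatenate(promo).mean()) if promo else float("nan")
        )
        site_truths.append(
            SiteTruth(
                position=site.position,
                configured_conservation=site.conservation,
                realised_y_fraction=y_fraction,
                realised_promoting_fraction=promoting_fraction,
                occupancy=float(nongap.mean()),
                is_decoy=site.is_decoy,
            )
        )
    truth = SyntheticTruth(
        sites=tuple(site_truths),
        anchor_columns=config.anchor_columns,
        clade_of=dict(zip(alignment.ids, labels)),
    )
    return alignment, clade_table, truth


@dataclass(frozen=True)
class RecoveryResult:
    """Averaged planted-site recovery over seeded replicates.

    ``sensitivity`` is marginal (all planted sites); ``sensitivity_qualified``
    conditions on sites whose realised column meets the stated quality
    bar (realised Y fraction and occupancy), which is the cohort the
    cut-off rules deterministically guarantee to recover.
    """

    sensitivity: float
    sensitivity_qualified: float
    false_positive_rate: float
    n_planted: int
    n_qualified: int
    n_decoys: int
    n_replicates: int
    per_site: tuple[dict, ...]


def recovery_experiment(
    config: FamilyConfig | None = None,
    rule: PredictionRule | None = None,
    n_replicates: int = 100,
    min_realised_conservation: float = 0.85,
    min_realised_occupancy: float = 0.9,
) -> RecoveryResult:
    """Run the full anchor→region→predict pipeline on seeded replicates.

    Replicate ``i`` uses seed ``config.seed + i``. A planted site counts
    as recovered when its alignment column is among the predicted columns
    of either terminal region; a decoy counts as a false positive when
    predicted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config = config or FamilyConfig()
    rule = rule or PredictionRule()
    per_site: list[dict] = []
    n_recovered = n_planted = 0
    n_qual_recovered = n_qualified = 0
    n_fp = n_decoys = 0
    for i in range(n_replicates):
        cfg = replace(config, seed=config.seed + i)
        alignment, _, truth = generate_family(cfg)
        anchors = find_anchor_cysteines(alignment)
        predicted_cols: set[int] = set()
        for region in (
            n_terminal_region(alignment, anchors),
            c_terminal_region(alignment, anchors),
        ):
            for rec in predict(region, rule):
                if rec.predicted:
                    # msa_column is already the parent-alignment column
                    predicted_cols.add(rec.msa_column)
        for site in truth.sites:
            hit = site.position in predicted_cols
            qualified = (
                not site.is_decoy
                and site.realised_y_fraction >= min_realised_conservation
                and site.occupancy >= min_realised_occupancy
            )
            per_site.append(
                {
                    "replicate": i,
                    "position": site.position,
                    "is_decoy": site.is_decoy,
                    "realised_y_fraction": site.realised_y_fraction,
                    "qualified": qualified,
                    "predicted": hit,
                }
            )
            if site.is_decoy:
                n_decoys += 1
                n_fp += hit
            else:
                n_planted += 1
                n_recovered += hit
                if qualified:
                    n_qualified += 1
                    n_qual_recovered += hit
    return RecoveryResult(
        sensitivity=n_recovered / n_planted if n_planted else float("nan"),
        sensitivity_qualified=(
            n_qual_recovered / n_qualified if n_qualified else float("nan")
        ),
        false_positive_rate=n_fp / n_decoys if n_decoys else float("nan"),
        n_planted=n_planted,
        n_qualified=n_qualified,
        n_decoys=n_decoys,
        n_replicates=n_replicates,
        per_site=tuple(per_site),
    )
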
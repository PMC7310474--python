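"""The synthetic family generator and the recovery harness."""

import dataclasses

import numpy as np
import pytest

from sulfoscan.msa_io import GAP
from sulfoscan.synthetic_data import (
    ConfigError,
    FamilyConfig,
    InsertionBlock,
    PlantedSite,
    generate_family,
    recovery_experiment,
)
from sulfoscan.taxonomy import subset_by_clade


def test_deterministic_under_seed():
    a1, _, t1 = generate_family(FamilyConfig(seed=5))
    a2, _, t2 = generate_family(FamilyConfig(seed=5))
    assert a1 == a2
    assert t1.sites == t2.sites
    a3, _, _ = generate_family(FamilyConfig(seed=6))
    assert a1 != a3


def test_degenerate_full_conservation_no_gaps():
    config = FamilyConfig(
        gap_rate=0.0,
        planted_sites=(PlantedSite(10, 1.0),),
        decoy_sites=(),
    )
    aln, _, truth = generate_family(config)
    mat = aln.matrix()
    assert (mat[:, 9] == "Y").all()
    assert truth.sites[0].realised_y_fraction == 1.0
    for col in config.anchor_columns:
        assert (mat[:, col - 1] == "C").all()
    assert not (mat == GAP).any()


def test_anchor_and_site_columns_gap_free_by_default():
    config = FamilyConfig(gap_rate=0.3, seed=2)
    aln, _, truth = generate_family(config)
    mat = aln.matrix()
    for col in list(config.anchor_columns) + [s.position for s in truth.sites]:
        assert (mat[:, col - 1] != GAP).all()


def test_clade_labels_match_config():
    config = FamilyConfig()
    _, clades, truth = generate_family(config)
    counts = clades.counts()
    for cls, n in config.n_per_class.items():
        assert counts[cls] == n


def test_insertion_block_dropped_in_other_clades():
    block = InsertionBlock(frozenset({"mammal", "reptile_bird"}), 45, 50)
    config = FamilyConfig(insertion_blocks=(block,), seed=9)
    aln, clades, _ = generate_family(config)
    mat = aln.matrix()
    labels = np.array([clades.label(i) for i in aln.ids])
    outside = ~np.isin(labels, ["mammal", "reptile_bird"])
    assert (mat[np.ix_(outside, np.arange(44, 50))] == GAP).all()
    # subsetting to a clade without the block drops those columns entirely:
    # amniote-only insertion vanishes from the tetrapods-minus-amniotes view
    from sulfoscan.taxonomy import CladeTable

    fish_ids = [i for i, l in zip(aln.ids, labels) if l == "ray_finned_fish"]
    fish_table = CladeTable({i: "ray_finned_fish" for i in fish_ids})
    _, fish_map = subset_by_clade(aln, fish_table, "jawed_vertebrates")
    assert not set(range(45, 51)) & set(fish_map.tolist())


def test_realised_fraction_tracks_configured_level():
    """Law of large numbers: planted level recovered within 3% at n=1000."""
    config = FamilyConfig(
        n_per_class={"mammal": 1000},
        planted_sites=(PlantedSite(10, 0.8),),
        decoy_sites=(),
        seed=1,
    )
    _, _, truth = generate_family(config)
    assert truth.sites[0].realised_y_fraction == pytest.approx(0.8, abs=0.03)


def test_site_near_edge_rejected():
    with pytest.raises(ConfigError, match="edge"):
        generate_family(
            FamilyConfig(planted_sites=(PlantedSite(3, 0.9),), decoy_sites=())
        )


def test_site_outside_regions_rejected():
    config = FamilyConfig()
    bad = config.n_region_length + 2  # inside the cysteine cluster
    with pytest.raises(ConfigError, match="region"):
        generate_family(
            FamilyConfig(planted_sites=(PlantedSite(bad, 0.9),), decoy_sites=())
        )


def test_c_region_sites_supported():
    config = FamilyConfig()
    pos = config.c_region_start + 10
    config = dataclasses.replace(
        config,
        planted_sites=(PlantedSite(pos, 0.95),),
        decoy_sites=(),
    )
    aln, _, truth = generate_family(config)
    assert truth.sites[0].realised_y_fraction >= 0.8
    result = recovery_experiment(config, n_replicates=3)
    assert result.sensitivity == 1.0


def test_recovery_fully_conserved_promoting():
    config = FamilyConfig(
        planted_sites=(PlantedSite(10, 1.0, promoting_fraction=1.0),),
        decoy_sites=(),
        gap_rate=0.0,
    )
    result = recovery_experiment(config, n_replicates=20)
    assert result.sensitivity == 1.0
    assert result.sensitivity_qualified == 1.0


def test_recovery_decoys_never_predicted():
    result = recovery_experiment(n_replicates=20)
    assert result.false_positive_rate == 0.0
    assert result.n_decoys == 40


def test_recovery_near_threshold_matches_binomial_band():
    """At a conservation level near the 75% cut the marginal sensitivity
    follows the binomial tail P(count >= ceil(0.745*n)) closely."""
    from scipy.stats import binom

    n = 60
    level = 0.76
    config = FamilyConfig(
        planted_sites=(PlantedSite(10, level, promoting_fraction=1.0),),
        decoy_sites=(),
        gap_rate=0.0,
        seed=100,
    )
    n_rep = 200
    result = recovery_experiment(config, n_replicates=n_rep)
    # predicted iff round_half_up(100*count/60) >= 75 <=> count >= 44.7 -> 45
    threshold = 45
    p_hit = 1 - binom.cdf(threshold - 1, n, level)
    se = (p_hit * (1 - p_hit) / n_rep) ** 0.5
    assert abs(result.sensitivity - p_hit) <= 4 * se + 1e-9


def test_truth_json_round_trip(tmp_path, default_family):
    import json

    _, _, truth = default_family
    path = truth.to_json(tmp_path / "truth.json")
    payload = json.loads(path.read_text())
    assert payload["anchor_columns"] == list(truth.anchor_columns)
    assert len(payload["sites"]) == len(truth.sites)
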
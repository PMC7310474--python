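"""The three cut-off rules, context ratios, and auxiliary flags."""

import dataclasses

import numpy as np
import pytest

from sulfoscan.conservation import ResidueClass, profile_columns, residue_class
from sulfoscan.msa_io import Alignment
from sulfoscan.regions import find_anchor_cysteines, n_terminal_region
from sulfoscan.sulfo_predict import (
    PredictionRule,
    aux_feature_flags,
    candidate_columns,
    context_ratio,
    predict,
    predicted_positions,
)
from sulfoscan.synthetic_data import (
    FamilyConfig,
    PlantedSite,
    generate_family,
)

from conftest import make_alignment


def column_stack(columns):
    """Alignment whose j-th column is columns[j] (equal-length strings)."""
    n = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    return make_alignment(rows)


def test_candidate_columns_threshold():
    # column 1: 4/5 Y = 80%; column 2: 3/5 Y = 60%
    aln = column_stack(["YYYYD", "YYYDD"])
    profiles = profile_columns(aln)
    assert candidate_columns(profiles) == [1]
    assert candidate_columns(profiles, PredictionRule(c1_min_y_percent=60)) == [1, 2]


def test_gaps_count_against_conservation():
    # 3/4 Y = 75% with the gap in the denominator
    aln = column_stack(["YYY-"])
    assert candidate_columns(profile_columns(aln)) == [1]
    aln2 = column_stack(["YY--"])
    assert candidate_columns(profile_columns(aln2)) == []


def test_context_ratio_all_promoting():
    cols = ["DDDD", "EEEE", "PPPP", "SSSS", "GGGG", "YYYY", "DDDD", "EEEE", "SSSS", "PPPP", "DDDD"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    n_pro, n_sup, ratio, used = context_ratio(profiles, 6)
    assert (n_pro, n_sup) == (10, 0)
    assert ratio == 1.0
    assert len(used) == 10


def test_context_ratio_direct_count():
    # consensi D,E,L,R,K,Y,F -> window of Y at position 6: D,E promoting;
    # L,R,K,F suppressing -> ratio 2/6
    cols = ["DDDD", "EEEE", "LLLL", "RRRR", "KKKK", "YYYY", "FFFF"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    n_pro, n_sup, ratio, _ = context_ratio(profiles, 6)
    assert (n_pro, n_sup) == (2, 4)
    assert ratio == pytest.approx(2 / 6)
    recs = predict(aln)
    assert recs[0].c2 is False


def test_neutral_columns_excluded_by_default():
    cols = ["QQQQ", "AAAA", "TTTT", "DDDD", "LLLL", "YYYY", "QQQQ"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    n_pro, n_sup, ratio, used = context_ratio(profiles, 6)
    assert (n_pro, n_sup) == (1, 1)
    assert ratio == 0.5
    # with neutral counted in the denominator the ratio drops
    # six context columns in the ±5 window (1-5 and 7); four are neutral
    rule = PredictionRule(neutral_excluded=False)
    _, _, ratio2, used2 = context_ratio(profiles, 6, rule)
    assert ratio2 == pytest.approx(1 / 6)
    assert len(used2) == 6


def test_all_neutral_window_is_indeterminate_pass():
    cols = ["QQQQ", "AAAA", "YYYY", "TTTT", "QQQQ"]
    aln = column_stack(cols)
    recs = predict(aln)
    (rec,) = [r for r in recs if r.position == 3]
    assert rec.indeterminate_context
    assert rec.promoting_ratio is None
    assert rec.c2 and rec.predicted


def test_low_occupancy_context_columns_excluded():
    # position 2 is mostly gaps: below the 0.5 occupancy floor, excluded
    cols = ["DDDD", "L---", "YYYY", "EEEE", "DDDD"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    n_pro, n_sup, ratio, used = context_ratio(profiles, 3)
    assert n_sup == 0
    assert 2 not in used


def test_c3_occupancy_gate():
    # 6/8 Y (75%) but occupancy 0.75... use a column with >=75% Y and low occupancy
    cols = ["YYY-", "DDDD", "EEEE"]
    aln = column_stack(cols)
    recs = predict(aln)
    (rec,) = [r for r in recs if r.position == 1]
    assert rec.c3  # occupancy 0.75 >= 0.5
    rule = PredictionRule(c3_min_occupancy=0.8)
    (rec2,) = [r for r in predict(aln, rule) if r.position == 1]
    assert not rec2.c3 and not rec2.predicted


def test_window_truncated_at_region_edges():
    cols = ["YYYY", "DDDD", "EEEE"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    _, _, _, used = context_ratio(profiles, 1)
    assert set(used) == {2, 3}


def test_own_column_never_in_window():
    cols = ["DDDD"] * 5 + ["YYYY"] + ["DDDD"] * 5
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    _, _, _, used = context_ratio(profiles, 6)
    assert 6 not in used


def test_aux_flags():
    # consensus context ...N D S... overlapping the +-7 window -> nglyc True
    cols = ["YYYY", "AAAA", "NNNN", "DDDD", "SSSS"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    cys, nglyc = aux_feature_flags(profiles, 1)
    assert nglyc and not cys
    cols2 = ["YYYY", "AAAA", "CCCC"]
    cys2, _ = aux_feature_flags(profile_columns(column_stack(cols2)), 1)
    assert cys2
    # N-P-S is not a sequon
    cols3 = ["YYYY", "NNNN", "PPPP", "SSSS"]
    _, nglyc3 = aux_feature_flags(profile_columns(column_stack(cols3)), 1)
    assert not nglyc3


def test_aux_flags_never_change_prediction():
    cols = ["DDDD"] * 5 + ["YYYY"] + ["DDDD", "NNNN", "DDDD", "SSSS", "CCCC"]
    aln = column_stack(cols)
    recs = predict(aln)
    (rec,) = [r for r in recs if r.position == 6]
    assert rec.cys_within_7 or rec.nglyc_motif_within_window
    assert rec.predicted  # flags advisory only


def test_all_alanine_region_empty():
    aln = make_alignment(["AAAA"] * 4)
    assert predict(aln) == []


def test_threshold_monotonicity_c1_c2(default_family):
    """Raising the conservation or context-ratio threshold never grows
    the predicted set (the occupancy threshold is not monotone: it also
    excludes context columns from the C2 window, see the next test)."""
    aln, _, _ = default_family
    region = n_terminal_region(aln, find_anchor_cysteines(aln))
    base = PredictionRule()
    base_set = set(predicted_positions(predict(region, base)))
    for change in ({"c1_min_y_percent": 85}, {"c2_min_promoting_ratio": 0.8}):
        tighter = dataclasses.replace(base, **change)
        assert set(predicted_positions(predict(region, tighter))) <= base_set
    for change in ({"c1_min_y_percent": 50}, {"c2_min_promoting_ratio": 0.2}):
        looser = dataclasses.replace(base, **change)
        assert set(predicted_positions(predict(region, looser))) >= base_set


def test_occupancy_threshold_reshapes_context_window():
    """Raising c3 can flip a C2-failing site to passing: excluding a
    low-occupancy suppressing column raises the promoting ratio."""
    # context: 2 promoting (full occupancy), 3 suppressing at 60% occupancy
    cols = ["DDDDD", "EEEEE", "LLL--", "RRR--", "KKK--", "YYYYY"]
    aln = column_stack(cols)
    profiles = profile_columns(aln)
    lo = PredictionRule(c3_min_occupancy=0.5)
    hi = PredictionRule(c3_min_occupancy=0.7)
    _, _, ratio_lo, _ = context_ratio(profiles, 6, lo)
    _, _, ratio_hi, _ = context_ratio(profiles, 6, hi)
    assert ratio_lo == pytest.approx(2 / 5) and ratio_lo < 0.5
    assert ratio_hi == pytest.approx(1.0) and ratio_hi >= 0.5


def test_row_order_invariance(default_family):
    aln, _, _ = default_family
    region = n_terminal_region(aln, find_anchor_cysteines(aln))
    rng = np.random.default_rng(0)
    perm = rng.permutation(aln.n_records)
    shuffled = Alignment(tuple(region.sub.records[i] for i in perm))
    assert predicted_positions(predict(region)) == predicted_positions(
        predict(shuffled)
    )


def test_synthetic_planted_recovery(default_family):
    """Planted sites predicted, decoys rejected, at the default seed."""
    aln, _, truth = default_family
    region = n_terminal_region(aln, find_anchor_cysteines(aln))
    hits = set(predicted_positions(predict(region)))
    planted = {s.position for s in truth.planted}
    decoys = {s.position for s in truth.decoys}
    assert planted <= hits
    assert hits & decoys == set()


def test_context_ratio_matches_brute_force_recount(default_family):
    """Window tallies equal an independent recount of consensus classes."""
    aln, _, truth = default_family
    region = n_terminal_region(aln, find_anchor_cysteines(aln))
    profiles = profile_columns(region)
    by_pos = {p.position: p for p in profiles}
    rule = PredictionRule()
    for site in truth.planted:
        n_pro, n_sup, ratio, _ = context_ratio(profiles, site.position, rule)
        pro = sup = 0
        for off in list(range(-5, 0)) + list(range(1, 6)):
            p = by_pos.get(site.position + off)
            if p is None or p.occupancy < 0.5 or p.consensus_residue is None:
                continue
            cls = residue_class(p.consensus_residue)
            if cls in (ResidueClass.TYR, ResidueClass.ACIDIC, ResidueClass.TURN):
                pro += 1
            elif cls in (ResidueClass.BASIC_HYDROPHOBIC, ResidueClass.CYS):
                sup += 1
        assert (n_pro, n_sup) == (pro, sup)


def test_promoting_suppressing_overlap_rejected():
    with pytest.raises(ValueError):
        PredictionRule(
            promoting_classes=frozenset({ResidueClass.TYR}),
            suppressing_classes=frozenset({ResidueClass.TYR}),
        )
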
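"""Segment linking and found/omitted/intruded accuracy arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dieteval.records import NutrientVector, Record, Segment
from dieteval.segmentation import (
    LinkedPair,
    MatchTable,
    SegmentationCoding,
    _pair_cost,
    link_segments,
    proportion_halfwidth,
    segmentation_accuracy,
)


def _seg(food_type, weight=100.0, label=None):
    return Segment(label=label or food_type, food_type=food_type, weight_g=weight,
                   nutrients=NutrientVector())


def _rec(rid, kind, segs, rtype=None):
    return Record(record_id=rid, record_kind=kind, segments=segs, record_type=rtype)


# ---------------------------------------------------------------- half-width

@pytest.mark.parametrize(
    "x, n, expected",
    [(302, 345, 3.5), (13, 31, 17.7), (345, 352, 1.5), (33, 33, 0.0)],
)
def test_halfwidth_reproduces_printed_cells(x, n, expected):
    assert round(proportion_halfwidth(x, n), 1) == expected


def test_halfwidth_needs_two_trials():
    with pytest.raises(ValueError):
        proportion_halfwidth(1, 1)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=1000), st.data())
def test_halfwidth_symmetric(n, data):
    x = data.draw(st.integers(min_value=0, max_value=n))
    assert proportion_halfwidth(x, n) == pytest.approx(proportion_halfwidth(n - x, n))


# ---------------------------------------------------------------- accuracy

def _coding(F, O, I):
    return SegmentationCoding(
        counts=pd.DataFrame({"F": [F], "O": [O], "I": [I], "n_true": [F + O]}, index=["all"])
    )


def test_accuracy_on_printed_totals():
    table = segmentation_accuracy(_coding(345, 7, 5), include_total=False)
    row = table.loc["all"]
    assert round(row.pct_found, 1) == 98.0 and round(row.hw_found, 1) == 1.5
    assert round(row.pct_omitted, 1) == 2.0
    assert round(row.pct_intruded, 1) == 1.4
    assert row.n_found == 345 and row.n_true == 352


def test_accuracy_perfect_stratum():
    row = segmentation_accuracy(_coding(33, 0, 0), include_total=False).loc["all"]
    assert row.pct_found == 100.0 and row.hw_found == 0.0 and row.pct_omitted == 0.0


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=300), st.integers(min_value=0, max_value=50),
       st.integers(min_value=0, max_value=50))
def test_found_plus_omitted_is_100(F, O, I):
    if F + O < 2:
        return
    row = segmentation_accuracy(_coding(F, O, I), include_total=False).loc["all"]
    assert row.pct_found + row.pct_omitted == pytest.approx(100.0)


def test_coding_rejects_inconsistent_counts():
    with pytest.raises(ValueError):
        SegmentationCoding(
            counts=pd.DataFrame({"F": [3], "O": [1], "I": [0], "n_true": [5]}, index=["a"])
        )


# ---------------------------------------------------------------- linking

def test_perfect_detection_links_everything(tax):
    segs = [_seg("pasta"), _seg("sauces"), _seg("leafy_vegetables")]
    ref = [_rec("r1", "food", segs)]
    app = [_rec("r1", "food", [s.model_copy() for s in segs])]
    table = link_segments(ref, app, tax)
    assert len(table.links) == 3 and not table.omissions and not table.intrusions


def test_added_dressing_is_intrusion(tax):
    ref = [_rec("r1", "food", [_seg("leafy_vegetables", label="salad")])]
    app = [_rec("r1", "food", [_seg("leafy_vegetables", label="salad"),
                               _seg("sauces", label="salad dressing", weight=20.0)])]
    table = link_segments(ref, app, tax)
    assert len(table.links) == 1
    assert table.intrusions == [("r1", 1)]


def test_missed_segment_is_omission(tax):
    ref = [_rec("r1", "food", [_seg("pasta"), _seg("sauces", weight=30.0)])]
    app = [_rec("r1", "food", [_seg("pasta")])]
    table = link_segments(ref, app, tax)
    assert table.omissions == [("r1", 1)]


def test_distant_types_stay_unlinked(tax):
    # beverage vs meat: different category, distance 3 > threshold
    ref = [_rec("r1", "food", [_seg("red_meat")])]
    app = [_rec("r1", "food", [_seg("tea_coffee")])]
    table = link_segments(ref, app, tax)
    assert not table.links
    assert table.omissions == [("r1", 0)] and table.intrusions == [("r1", 0)]


def _brute_force(ref_segs, app_segs, tax):
    """Exhaustive max-cardinality, min-cost matching under the linking cost."""
    n, m = len(ref_segs), len(app_segs)
    best = (0, 0.0, frozenset())
    for k in range(min(n, m), -1, -1):
        found = None
        for ref_subset in itertools.combinations(range(n), k):
            for app_perm in itertools.permutations(range(m), k):
                costs = [_pair_cost(ref_segs[i], app_segs[j], tax)
                         for i, j in zip(ref_subset, app_perm)]
                if any(c >= 1e6 for c in costs):
                    continue
                total = sum(costs)
                if found is None or total < found[0]:
                    found = (total, frozenset(zip(ref_subset, app_perm)))
        if found is not None:
            return k, found[0], found[1]
    return 0, 0.0, frozenset()


@pytest.mark.parametrize("seed", range(8))
def test_linking_matches_exhaustive_oracle(tax, seed):
    rng = np.random.default_rng(seed)
    types = sorted(tax.types)
    n, m = rng.integers(1, 5, size=2)
    ref_segs = [_seg(str(rng.choice(types)), weight=float(rng.uniform(10, 300)))
                for _ in range(n)]
    app_segs = [_seg(str(rng.choice(types)), weight=float(rng.uniform(10, 300)))
                for _ in range(m)]
    ref = [_rec("r", "food", ref_segs)]
    app = [_rec("r", "food", app_segs)]
    table = link_segments(ref, app, tax)
    k, cost, pairs = _brute_force(ref_segs, app_segs, tax)
    got_pairs = frozenset((l.ref_idx, l.app_idx) for l in table.links)
    got_cost = sum(_pair_cost(ref_segs[i], app_segs[j], tax) for i, j in got_pairs)
    assert len(got_pairs) == k
    assert got_cost == pytest.approx(cost)


def test_linking_record_order_invariance(tax, small_study):
    ref, app, _ = small_study
    fwd = link_segments(ref, app, tax).to_frame()
    rev = link_segments(ref[::-1], app[::-1], tax).to_frame()
    pd.testing.assert_frame_equal(
        fwd.sort_values(["record_id", "ref_idx", "app_idx"]).reset_index(drop=True),
        rev.sort_values(["record_id", "ref_idx", "app_idx"]).reset_index(drop=True),
    )


def test_manual_links_override(tax):
    # two same-type candidates: force the crossed pairing
    ref = [_rec("r1", "food", [_seg("pasta", 100.0), _seg("pasta", 200.0)])]
    app = [_rec("r1", "food", [_seg("pasta", 100.0), _seg("pasta", 200.0)])]
    manual = [LinkedPair("r1", 0, 1), LinkedPair("r1", 1, 0)]
    table = link_segments(ref, app, tax, manual_links=manual)
    assert {(l.ref_idx, l.app_idx) for l in table.links} == {(0, 1), (1, 0)}


def test_conflicting_manual_links_rejected(tax):
    ref = [_rec("r1", "food", [_seg("pasta"), _seg("rice")])]
    app = [_rec("r1", "food", [_seg("pasta"), _seg("rice")])]
    with pytest.raises(ValueError, match="conflicting"):
        link_segments(ref, app, tax,
                      manual_links=[LinkedPair("r1", 0, 0), LinkedPair("r1", 0, 1)])


def test_manual_link_unknown_record_rejected(tax):
    ref = [_rec("r1", "food", [_seg("pasta")])]
    app = [_rec("r1", "food", [_seg("pasta")])]
    with pytest.raises(ValueError, match="unknown record_id"):
        link_segments(ref, app, tax, manual_links=[LinkedPair("zzz", 0, 0)])


def test_match_table_frame_round_trip(tax, small_study):
    ref, app, _ = small_study
    table = link_segments(ref, app, tax)
    rebuilt = MatchTable.from_frame(table.to_frame())
    assert rebuilt.to_frame().equals(table.to_frame())
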
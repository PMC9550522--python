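"""Sliding-window detection: window test, region assembly, merging, filters."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polyxy import (
    ProteinRecord,
    ScanParams,
    apply_filters,
    classify_region,
    detect_regions,
    merge_close_regions,
    window_is_positive,
)
from polyxy.synthetic import brute_force_regions

from oracle_utils import protein


@pytest.mark.parametrize(
    "window_seq, expected",
    [
        ("VVVGGG", ("G", "V")),  # three V, three G: positive
        ("AAAAAA", None),  # homorepeat: one residue type
        ("AAAAAG", None),  # second type occurs only once
        ("AAGGGS", None),  # three residue types
        ("AAGGXX", None),  # X is the ambiguity code, not a standard residue
        ("AAGG**", None),  # stop characters disqualify the window
        ("GGSSSS", ("G", "S")),
    ],
)
def test_window_positivity(window_seq, expected):
    assert window_is_positive(window_seq) == expected


def test_smn_polysg_region_detected_at_printed_coordinates():
    """The SMN N-terminal polySG 'SSGGSGG' spans positions 4-10."""
    # synthetic carrier: the documented 7-mer at positions 4-10, guarded flanks
    p = protein("MAM" + "SSGGSGG" + "WDDTAL")
    regions = detect_regions(p)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end, r.pair, r.sequence) == (4, 10, ("G", "S"), "SSGGSGG")


def test_homorepeat_is_not_polyxy():
    assert detect_regions(protein("AAAAAAAA")) == []


def test_overlapping_regions_of_different_pairs_stay_separate():
    regions = detect_regions(protein("AAAGGGSSS"))
    spans = [(r.start, r.end, r.pair) for r in regions]
    assert spans == [(1, 6, ("A", "G")), (4, 9, ("G", "S"))]


def test_short_and_empty_sequences_give_no_regions():
    assert detect_regions(protein("AGAGA")) == []  # below window length


def test_region_invariants_on_random_sequences():
    rng = np.random.default_rng(7)
    params = ScanParams()
    for _ in range(50):
        seq = "".join(rng.choice(list("AGSDE"), size=200))
        for r in detect_regions(protein(seq), params):
            counts = {a: r.sequence.count(a) for a in set(r.sequence)}
            assert set(counts) == set(r.pair)
            assert all(v >= 2 for v in counts.values())
            assert len(r) >= params.window


def test_maximality_no_positive_window_extends_beyond_its_region():
    rng = np.random.default_rng(11)
    w = 6
    for _ in range(30):
        seq = "".join(rng.choice(list("AGS"), size=120))
        p = protein(seq)
        regions = detect_regions(p)
        by_pair = {}
        for r in regions:
            by_pair.setdefault(r.pair, []).append((r.start, r.end))
        for i in range(len(seq) - w + 1):
            pair = window_is_positive(seq[i : i + w])
            if pair is None:
                continue
            ws, we = i + 1, i + w
            # the positive window must be fully contained in a same-pair region
            assert any(s <= ws and we <= e for s, e in by_pair[pair])


@given(
    st.integers(min_value=0, max_value=2**31 - 1),
    st.integers(min_value=1, max_value=300),
    st.integers(min_value=2, max_value=20),
)
def test_detector_equals_brute_force_oracle(seed, length, alpha_size):
    """The linear-sweep detector agrees exactly with the naive fixpoint oracle."""
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")[:alpha_size]
    p = protein("".join(rng.choice(alphabet, size=length)))
    got = detect_regions(p)
    exp = brute_force_regions(p)
    assert got == exp


def test_detection_is_deterministic():
    p = protein("GGSSGGASSGGSSAGAGAGAHHKK")
    assert detect_regions(p) == detect_regions(p)


def test_merge_close_regions_bridges_single_foreign_residue():
    p = protein("GGSSGGASSGGSS")
    regions = detect_regions(p)
    assert [(r.start, r.end) for r in regions] == [(1, 6), (8, 13)]
    merged = merge_close_regions(regions, p, merge_gap=1)
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end, merged[0].sequence) == (1, 13, "GGSSGGASSGGSS")


def test_merge_never_joins_different_pairs():
    p = protein("AAGGAG" + "KW" + "GGSSGS")
    regions = detect_regions(p)
    assert [r.pair for r in regions] == [("A", "G"), ("G", "S")]
    merged = merge_close_regions(regions, p, merge_gap=2)
    assert merged == sorted(regions, key=lambda r: (r.start, r.end, r.pair))


def test_merge_gap_outside_range_is_an_error():
    p = protein("GGSSGGASSGGSS")
    with pytest.raises(ValueError):
        merge_close_regions(detect_regions(p), p, merge_gap=0)
    with pytest.raises(ValueError):
        merge_close_regions(detect_regions(p), p, merge_gap=3)


def test_scan_params_validation():
    with pytest.raises(ValueError):
        ScanParams(window=3)
    with pytest.raises(ValueError):
        ScanParams(merge_gap=3)
    with pytest.raises(ValueError):
        ScanParams(pair_filter=("G", None))
    with pytest.raises(ValueError):
        ScanParams(category_filter=frozenset({"weird"}))


def _classified(seq, start=1):
    p = protein(seq)
    return [classify_region(r) for r in detect_regions(p)]


def test_filters_by_pair_category_and_min_units():
    regions = (
        _classified("GLGLGLGL")  # direpeat GL, 4 units
        + _classified("GLGLGL")  # direpeat GL, 3 units
        + _classified("VVVGGG")  # joined VG
        + _classified("SSGGSGG")  # shuffled GS
    )
    exact = apply_filters(regions, ScanParams(pair_filter=("G", "L")))
    assert [r.pair for r in exact] == [("G", "L"), ("G", "L")]

    any_x = apply_filters(regions, ScanParams(pair_filter=(None, "G")))
    assert len(any_x) == 4  # every pair here contains G

    any_s = apply_filters(regions, ScanParams(pair_filter=(None, "S")))
    assert [r.pair for r in any_s] == [("G", "S")]

    cats = apply_filters(regions, ScanParams(category_filter=frozenset({"joined"})))
    assert [r.category for r in cats] == ["joined"]

    units = apply_filters(regions, ScanParams(min_units=4))
    assert [r.n_units for r in units] == [4]  # non-direpeats dropped
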
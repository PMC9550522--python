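"""Containment in annotations and the random-placement baseline."""

import numpy as np
import pytest
from scipy import stats

from polyxy import (
    AnnotationInterval,
    ProteinRecord,
    overlap_analysis,
    random_placement,
    region_contained,
    scan_proteins,
)


def _region(pid="P", start=10, end=15):
    from polyxy import PolyXYRegion

    return PolyXYRegion(
        protein_id=pid, start=start, end=end,
        pair=("G", "S"), sequence="S" * 2 + "G" * (end - start - 1),
        category="shuffled",
    )


@pytest.mark.parametrize(
    "interval, expected",
    [
        ((1, 50), True),  # full containment
        ((12, 50), False),  # partial overlap is not containment
        ((10, 15), True),  # boundary-inclusive
        ((16, 40), False),  # disjoint
    ],
)
def test_containment_requires_complete_region(interval, expected):
    r = _region(start=10, end=15)
    iv = AnnotationInterval("P", interval[0], interval[1], "domain", "D1")
    assert region_contained(r, [iv]) is expected


def test_containment_is_monotone_under_interval_growth():
    r = _region(start=10, end=15)
    for s in range(1, 11):
        for e in range(15, 30):
            small = AnnotationInterval("P", s, e, "domain", "")
            grown = AnnotationInterval("P", max(1, s - 1), e + 1, "domain", "")
            if region_contained(r, [small]):
                assert region_contained(r, [grown])


def test_random_placement_properties():
    protein = ProteinRecord("P", "A" * 100)
    r = _region(start=10, end=15)
    rng = np.random.default_rng(0)
    placements = [random_placement(r, protein, rng) for _ in range(10000)]
    starts = np.array([p.start for p in placements])
    assert starts.min() >= 1 and starts.max() <= 95
    assert all(p.end - p.start == 5 for p in placements)
    # uniformity over the 95 admissible starts
    counts = np.bincount(starts, minlength=96)[1:]
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert stats.chi2.sf(chi2, df=94) > 0.01


def test_random_placement_whole_protein_and_reproducibility():
    protein = ProteinRecord("P", "S" * 6)
    r = _region(start=1, end=6)
    placement = random_placement(r, protein, np.random.default_rng(1))
    assert (placement.start, placement.end) == (1, 6)

    long_protein = ProteinRecord("P", "A" * 80)
    a = [random_placement(r, long_protein, np.random.default_rng(42)) for _ in range(20)]
    b = [random_placement(r, long_protein, np.random.default_rng(42)) for _ in range(20)]
    assert a == b


def _toy_dataset():
    proteins = [
        ProteinRecord("P1", "MKL" + "SSGGSGG" + "WDE" * 10),
        ProteinRecord("P2", "KK" + "VVVGGG" + "DDEW" * 8),
    ]
    regions = scan_proteins(proteins)
    assert len(regions) == 2
    return proteins, regions


def test_total_coverage_gives_fraction_one_everywhere():
    proteins, regions = _toy_dataset()
    annotations = [
        AnnotationInterval(p.id, 1, len(p), kind, "all")
        for p in proteins
        for kind in ("domain", "disorder")
    ]
    report = overlap_analysis(regions, proteins, annotations, n_random=5, seed=0)
    assert (report.table["observed_fraction"] == 1.0).all()
    assert (report.table["random_fraction"] == 1.0).all()
    assert (report.table["p"] == 1.0).all()


def test_no_annotations_in_common_is_an_error():
    proteins, regions = _toy_dataset()
    annotations = [AnnotationInterval("P1", 1, 10, "domain", "")]
    other = [AnnotationInterval("ELSEWHERE", 1, 10, "domain", "")]
    with pytest.raises(ValueError, match="no annotated protein"):
        overlap_analysis(regions, proteins, other, seed=0)
    # a subset of the proteins being annotated is fine
    overlap_analysis(regions, proteins, annotations, seed=0)


def test_unannotated_proteins_count_unless_restricted():
    proteins, regions = _toy_dataset()
    annotations = [AnnotationInterval("P1", 1, len(proteins[0]), "disorder", "")]
    full = overlap_analysis(regions, proteins, annotations, seed=0)
    restricted = overlap_analysis(regions, proteins, annotations, seed=0, annotated_only=True)
    assert set(full.table["pair"]) == {"GS", "GV"}
    assert set(restricted.table["pair"]) == {"GS"}


def test_report_is_reproducible_with_fixed_seed():
    proteins, regions = _toy_dataset()
    annotations = [AnnotationInterval("P1", 2, 20, "disorder", "")]
    r1 = overlap_analysis(regions, proteins, annotations, n_random=3, seed=7)
    r2 = overlap_analysis(regions, proteins, annotations, n_random=3, seed=7)
    assert r1.table.equals(r2.table)


def test_random_containment_converges_to_analytic_expectation():
    """For one interval of length m in a protein of length L and region
    length k, the containment probability of a uniform placement is
    max(0, m - k + 1) / (L - k + 1)."""
    L, m, k = 120, 40, 6
    protein = ProteinRecord("P1", "MKL" + "SSGGSGG" + "A" * (L - 10))
    region = scan_proteins([protein])[0]
    assert len(region) == 7
    k = len(region)
    annotations = [AnnotationInterval("P1", 30, 30 + m - 1, "disorder", "")]
    n_random = 1000
    report = overlap_analysis([region], [protein], annotations, n_random=n_random, seed=5)
    expected = (m - k + 1) / (len(protein) - k + 1)
    row = report.table[report.table["kind"] == "disorder"].iloc[0]
    se = np.sqrt(expected * (1 - expected) / n_random)
    assert abs(row["random_fraction"] - expected) < 3 * se + 1e-12
    assert row["observed_fraction"] == 0.0
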
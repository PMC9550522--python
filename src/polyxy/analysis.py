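"""Summary statistics over sets of classified polyXY regions.

Covers the per-dataset totals and ratios, category proportions, amino-acid
usage versus proteome background, relative positional profiles, direpeat
unit-count distributions, and joined-order counts and their positional
comparison (two-sided Mann-Whitney U).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import PolyXYRegion
from .detect import STANDARD_AA, ProteinRecord

__all__ = [
    "DatasetSummary",
    "summarize_dataset",
    "composition_usage",
    "relative_positions",
    "compare_order_positions",
    "unit_distribution",
    "joined_order_counts",
]

UNIT_BINS = ("3", "4", "5", "6", ">6")


@dataclass(frozen=True)
class DatasetSummary:
    """Dataset-level totals, analogous to one column of a per-taxon table.

    ``ratio_region_residues_per_protein_residues`` divides the total number
    of residues inside polyXY regions by the total number of protein
    residues; overlapping regions of different pairs each contribute their
    own residues.  When ``n_regions`` is 0, ``mean_region_length`` is
    reported as 0.0 and the category fractions as 0.
    """

    n_proteins: int
    n_residues: int
    n_regions: int
    ratio_regions_per_protein: float
    ratio_region_residues_per_protein_residues: float
    mean_region_length: float
    category_fractions: Mapping[str, float]

    def to_series(self) -> pd.Series:
        d = {
            "n_proteins": self.n_proteins,
            "n_residues": self.n_residues,
            "n_regions": self.n_regions,
            "ratio_regions_per_protein": self.ratio_regions_per_protein,
            "ratio_region_residues_per_protein_residues": self.ratio_region_residues_per_protein_residues,
            "mean_region_length": self.mean_region_length,
        }
        for cat in ("direpeat", "joined", "shuffled"):
            d[f"fraction_{cat}"] = self.category_fractions[cat]
        return pd.Series(d)


def summarize_dataset(
    proteins: Sequence[ProteinRecord], regions: Sequence[PolyXYRegion]
) -> DatasetSummary:
    """Compute dataset-level totals and category proportions."""
    if not proteins:
        raise ValueError("summarize_dataset requires at least one protein")
    n_proteins = len(proteins)
    n_residues = sum(len(p) for p in proteins)
    n_regions = len(regions)
    region_residues = sum(len(r) for r in regions)
    cat_counts = Counter(r.category for r in regions)
    if n_regions:
        fractions = {c: cat_counts.get(c, 0) / n_regions for c in ("direpeat", "joined", "shuffled")}
        mean_len = region_residues / n_regions
    else:
        fractions = {c: 0.0 for c in ("direpeat", "joined", "shuffled")}
        mean_len = 0.0
    return DatasetSummary(
        n_proteins=n_proteins,
        n_residues=n_residues,
        n_regions=n_regions,
        ratio_regions_per_protein=n_regions / n_proteins,
        ratio_region_residues_per_protein_residues=region_residues / n_residues,
        mean_region_length=mean_len,
        category_fractions=fractions,
    )


def composition_usage(
    proteins: Sequence[ProteinRecord], regions: Sequence[PolyXYRegion]
) -> pd.DataFrame:
    """Per amino acid: background frequency vs fraction of regions using it.

    ``background_frequency`` is the residue frequency over all protein
    sequences (normalized over the 20 standard amino acids).
    ``region_fraction`` is the fraction of regions whose pair contains the
    amino acid, so each region is counted once per pair member and the
    column sums to 2 when every region pair is standard.
    """
    if not proteins:
        raise ValueError("composition_usage requires at least one protein")
    aas = sorted(STANDARD_AA)
    counts = Counter()
    for p in proteins:
        counts.update(p.sequence)
    total = sum(counts[a] for a in aas)
    if total == 0:
        raise ValueError("no standard residues in input proteins")
    background = np.array([counts[a] / total for a in aas])

    pair_counts = Counter()
    for r in regions:
        for a in r.pair:
            pair_counts[a] += 1
    n_regions = len(regions)
    region_fraction = np.array(
        [pair_counts[a] / n_regions if n_regions else 0.0 for a in aas]
    )
    return pd.DataFrame(
        {"background_frequency": background, "region_fraction": region_fraction},
        index=pd.Index(aas, name="amino_acid"),
    )


def relative_positions(
    regions: Sequence[PolyXYRegion], proteins: Sequence[ProteinRecord]
) -> np.ndarray:
    """Relative position of each region: midpoint / protein length, in (0, 1)."""
    lengths = {p.id: len(p) for p in proteins}
    out = np.empty(len(regions))
    for i, r in enumerate(regions):
        if r.protein_id not in lengths:
            raise KeyError(f"region protein {r.protein_id!r} not among the supplied proteins")
        out[i] = (r.start + r.end) / 2 / lengths[r.protein_id]
    return out


def compare_order_positions(positions_a, positions_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two relative-position samples.

    Exact null distribution for small samples without ties, normal
    approximation with tie correction otherwise (scipy's 'auto' policy).
    Returns (U, p) with U computed for the first sample.
    """
    a = np.asarray(positions_a, dtype=float)
    b = np.asarray(positions_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both position samples must be non-empty")
    if a.size and b.size and np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        # degenerate all-tied case: no evidence of a shift
        return a.size * b.size / 2, 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def unit_distribution(direpeats: Sequence[PolyXYRegion]) -> tuple[pd.Series, float]:
    """Histogram of direpeat unit counts over bins {3, 4, 5, 6, >6}.

    Returns (counts, fraction of direpeats with more than 3 units).
    Every input must be a direpeat.
    """
    counts = dict.fromkeys(UNIT_BINS, 0)
    low_bins: dict[str, int] = {}  # only reachable with window < 6
    n_gt3 = 0
    for r in direpeats:
        if r.category != "direpeat":
            raise ValueError(f"unit_distribution requires direpeats, got {r.category!r}")
        if r.n_units < 3:
            low_bins[str(r.n_units)] = low_bins.get(str(r.n_units), 0) + 1
        else:
            counts[str(r.n_units) if r.n_units <= 6 else ">6"] += 1
        if r.n_units > 3:
            n_gt3 += 1
    counts = {**dict(sorted(low_bins.items())), **counts}
    series = pd.Series(counts, name="n_regions")
    series.index.name = "n_units"
    fraction_gt3 = n_gt3 / len(direpeats) if direpeats else 0.0
    return series, fraction_gt3


def joined_order_counts(joined_regions: Sequence[PolyXYRegion]) -> Counter:
    """Counts of joined regions keyed by ordered (first-run, second-run) pair."""
    counts: Counter = Counter()
    for r in joined_regions:
        if r.category != "joined":
            raise ValueError(f"joined_order_counts requires joined regions, got {r.category!r}")
        counts[r.joined_order] += 1
    return counts
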
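"""Containment of polyXY regions in domain / disorder annotations.

A region "overlaps" an annotation only when the complete region lies
inside the annotated interval (boundary-inclusive).  The observed
containment fraction per amino-acid pair is contrasted with a baseline in
which, for each region, an equally long segment is placed uniformly at
random within the same protein; the two samples of per-region containment
indicators are compared with a two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .analysis import compare_order_positions
from .classify import PolyXYRegion
from .detect import ProteinRecord, RegionSpan
from .io import ANNOTATION_KINDS, AnnotationInterval

__all__ = ["region_contained", "random_placement", "overlap_analysis", "OverlapReport"]


@dataclass(frozen=True)
class OverlapReport:
    """Observed vs random containment fractions, per pair and annotation kind.

    ``table`` has one row per (pair, kind) with columns observed_fraction,
    random_fraction, U, p, n_regions, n_random; ``seed`` is the random seed
    that makes the baseline reproducible.
    """

    table: pd.DataFrame
    n_random: int
    seed: Optional[int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def region_contained(region, intervals: Sequence[AnnotationInterval]) -> bool:
    """True iff some interval fully contains [region.start, region.end]."""
    return any(iv.start <= region.start and region.end <= iv.end for iv in intervals)


def random_placement(
    region, protein: ProteinRecord, rng: np.random.Generator
) -> RegionSpan:
    """Place a segment of the region's length uniformly at random in its protein."""
    k = region.end - region.start + 1
    L = len(protein)
    if L < k:
        raise ValueError(f"protein {protein.id!r} (length {L}) shorter than region length {k}")
    start = int(rng.integers(1, L - k + 2))  # 1-based start in [1, L-k+1]
    return RegionSpan(
        protein_id=protein.id,
        start=start,
        end=start + k - 1,
        pair=region.pair,
        sequence=protein.sequence[start - 1 : start + k - 1],
    )


def overlap_analysis(
    regions: Sequence[PolyXYRegion],
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[AnnotationInterval],
    n_random: int = 1,
    seed: Optional[Union[int, np.random.Generator]] = None,
    pairs: Optional[Sequence[tuple]] = None,
    annotated_only: bool = False,
) -> OverlapReport:
    """Observed vs random-baseline containment, per pair and annotation kind.

    Parameters
    ----------
    n_random : int
        Random placements drawn per region (default 1; the mean of their
        containment indicators forms the baseline sample).
    seed : int, numpy Generator or None
        Source of randomness; placements are drawn per region in input
        order, so a fixed seed makes the whole report bit-reproducible.
    pairs : sequence of 2-tuples, optional
        Restrict the report to these amino-acid pairs (e.g. the most
        prevalent ones); default is every pair present in ``regions``.
    annotated_only : bool
        If True, drop regions on proteins without any annotation record;
        by default such regions count as not contained, since absence of
        annotation is itself informative in a proteome-wide setting.
    """
    if n_random < 1:
        raise ValueError(f"n_random must be >= 1, got {n_random}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    proteins_by_id = {p.id: p for p in proteins}
    for r in regions:
        if r.protein_id not in proteins_by_id:
            raise KeyError(f"region protein {r.protein_id!r} not among the supplied proteins")

    by_protein_kind: dict[tuple[str, str], list[AnnotationInterval]] = {}
    annotated_ids = set()
    for iv in annotations:
        by_protein_kind.setdefault((iv.protein_id, iv.kind), []).append(iv)
        annotated_ids.add(iv.protein_id)
    if annotations and not (annotated_ids & set(r.protein_id for r in regions)):
        raise ValueError("no annotated protein in common with the regions")

    if annotated_only:
        regions = [r for r in regions if r.protein_id in annotated_ids]

    # Per region: observed indicator and mean of n_random placement
    # indicators, for each annotation kind.  Placements are shared across
    # kinds (one random segment, checked against both), as one baseline
    # segment per region is drawn.
    obs: dict[str, list[int]] = {k: [] for k in ANNOTATION_KINDS}
    rand: dict[str, list[float]] = {k: [] for k in ANNOTATION_KINDS}
    region_pairs: list[tuple] = []
    for r in regions:
        protein = proteins_by_id[r.protein_id]
        region_pairs.append(r.pair)
        placements = [random_placement(r, protein, rng) for _ in range(n_random)]
        for kind in ANNOTATION_KINDS:
            ivs = by_protein_kind.get((r.protein_id, kind), [])
            obs[kind].append(int(region_contained(r, ivs)))
            rand[kind].append(
                float(np.mean([region_contained(p, ivs) for p in placements]))
            )

    if pairs is None:
        wanted = sorted(set(region_pairs))
    else:
        wanted = [tuple(sorted(p)) for p in pairs]

    rows = []
    region_pairs_arr = np.array(["".join(p) for p in region_pairs])
    for pair in wanted:
        mask = region_pairs_arr == "".join(pair)
        n = int(mask.sum())
        if n == 0:
            continue
        for kind in ANNOTATION_KINDS:
            o = np.asarray(obs[kind], dtype=float)[mask]
            b = np.asarray(rand[kind], dtype=float)[mask]
            U, p = compare_order_positions(o, b)
            rows.append(
                {
                    "pair": "".join(pair),
                    "kind": kind,
                    "observed_fraction": float(o.mean()),
                    "random_fraction": float(b.mean()),
                    "U": U,
                    "p": p,
                    "n_regions": n,
                    "n_random": n_random,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["pair", "kind", "observed_fraction", "random_fraction", "U", "p", "n_regions", "n_random"],
    )
    return OverlapReport(table=table, n_random=n_random, seed=seed if isinstance(seed, int) else None)
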
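"""Sliding-window detection of polyXY regions.

A polyXY is a protein region composed of exactly two amino-acid types.  A
fixed-length window (default 6 residues, which doubles as the minimum
reportable region length) slides over the sequence one position at a time;
a window is *positive* when it contains exactly two distinct standard
residues and each of them occurs at least twice.  Overlapping positive
windows of the same unordered pair are unioned into maximal regions.
Regions of *different* pairs may overlap each other.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "STANDARD_AA",
    "ProteinRecord",
    "ScanParams",
    "RegionSpan",
    "window_is_positive",
    "detect_regions",
    "merge_close_regions",
    "apply_filters",
]

#: The 20 standard amino acids.  Ambiguity codes (B, J, X, Z), the rare
#: translated residues (O, U), stops ('*') and gaps make a window negative:
#: an ambiguous composition cannot define a bona fide polyXY.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    Parameters
    ----------
    id : str
        Identifier; for FASTA input, the first whitespace-delimited header
        token.  Must be unique within one input file.
    sequence : str
        Upper-case amino-acid sequence, length >= 1.  Non-standard letters
        are tolerated in the sequence; windows touching them are simply
        never positive.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScanParams:
    """Parameters of a polyXY scan.

    Attributes
    ----------
    window : int
        Sliding-window length; also the minimum reportable region length.
        Must be >= 4 (two residue types each occurring twice is impossible
        below 4).  Default 6.
    merge_gap : int
        Merge regions of the same pair separated by at most this many
        residues (residues other than X or Y).  0 disables merging.
    pair_filter : tuple or None
        ``("G", "V")`` keeps only regions of the unordered pair {G, V};
        ``(None, "S")`` keeps regions whose pair contains S ("any X,
        specific Y").
    category_filter : frozenset or None
        Subset of {"direpeat", "joined", "shuffled"} to retain.
    min_units : int or None
        Keep only direpeats with at least this many repeated units
        (non-direpeats are dropped when set).
    """

    window: int = 6
    merge_gap: int = 0
    pair_filter: Optional[tuple] = None
    category_filter: Optional[frozenset] = None
    min_units: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError(f"window must be >= 4, got {self.window}")
        if self.merge_gap not in (0, 1, 2):
            raise ValueError(f"merge_gap must be 0, 1 or 2, got {self.merge_gap}")
        if self.min_units is not None and self.min_units < 1:
            raise ValueError(f"min_units must be >= 1, got {self.min_units}")
        if self.pair_filter is not None:
            x, y = self.pair_filter
            if y is None:
                raise ValueError("pair_filter second element (Y) must be a residue")
            aa = [a for a in (x, y) if a is not None]
            bad = [a for a in aa if a not in STANDARD_AA]
            if bad:
                raise ValueError(f"pair_filter residues must be standard amino acids: {bad}")
        if self.category_filter is not None:
            bad = set(self.category_filter) - {"direpeat", "joined", "shuffled"}
            if bad:
                raise ValueError(f"unknown categories in category_filter: {sorted(bad)}")


@dataclass(frozen=True)
class RegionSpan:
    """A detected polyXY region (1-based, inclusive coordinates).

    ``pair`` is the unordered amino-acid pair stored as an alphabetically
    sorted 2-tuple, e.g. ``("G", "S")``.
    """

    protein_id: str
    start: int
    end: int
    pair: tuple
    sequence: str

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValueError(f"invalid span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match span")
        if len(self.pair) != 2 or tuple(sorted(self.pair)) != tuple(self.pair):
            raise ValueError(f"pair must be a sorted 2-tuple, got {self.pair!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


def window_is_positive(window_seq: str) -> Optional[tuple]:
    """Test one window; return the unordered pair (sorted 2-tuple) or None.

    Positive iff exactly two distinct residue types occur and each occurs
    at least twice, both being standard amino acids.
    """
    counts = Counter(window_seq)
    if len(counts) != 2:
        return None
    (a, na), (b, nb) = sorted(counts.items())
    if na < 2 or nb < 2:
        return None
    if a not in STANDARD_AA or b not in STANDARD_AA:
        return None
    return (a, b)


def detect_regions(protein: ProteinRecord, params: ScanParams = ScanParams()) -> list[RegionSpan]:
    """Scan one protein and return maximal polyXY regions.

    Positive windows of the same pair are unioned whenever they overlap
    (share at least one position); windows of different pairs never merge,
    so regions of different pairs may overlap in the output.  Regions are
    sorted by (start, end, pair).  Gap merging (``params.merge_gap``) is a
    separate step, see :func:`merge_close_regions`.
    """
    seq = protein.sequence
    w = params.window
    if len(seq) < w:
        return []

    # 0-based positive window start positions, grouped per pair; starts are
    # generated in increasing order so each group is already sorted.
    positives: dict[tuple, list[int]] = {}
    for i in range(len(seq) - w + 1):
        pair = window_is_positive(seq[i : i + w])
        if pair is not None:
            positives.setdefault(pair, []).append(i)

    regions: list[RegionSpan] = []
    for pair, starts in positives.items():
        run_start = starts[0]
        run_end = starts[0] + w - 1  # inclusive, 0-based
        for i in starts[1:]:
            if i <= run_end:  # strict overlap: shares >= 1 position
                run_end = i + w - 1
            else:
                regions.append(_make_region(protein, run_start, run_end, pair))
                run_start, run_end = i, i + w - 1
        regions.append(_make_region(protein, run_start, run_end, pair))

    regions.sort(key=lambda r: (r.start, r.end, r.pair))
    return regions


def _make_region(protein: ProteinRecord, start0: int, end0: int, pair: tuple) -> RegionSpan:
    return RegionSpan(
        protein_id=protein.id,
        start=start0 + 1,
        end=end0 + 1,
        pair=pair,
        sequence=protein.sequence[start0 : end0 + 1],
    )


def merge_close_regions(
    regions: Sequence[RegionSpan], protein: ProteinRecord, merge_gap: int
) -> list[RegionSpan]:
    """Merge same-pair regions separated by at most ``merge_gap`` residues.

    ``regions`` must be the :func:`detect_regions` output for ``protein``.
    The intervening residues are, by construction of maximal regions,
    outside the pair.  Merging is transitive left-to-right; regions of
    different pairs never merge.  ``merge_gap`` must be 1 or 2.
    """
    if merge_gap not in (1, 2):
        raise ValueError(f"merge_gap must be 1 or 2, got {merge_gap}")

    by_pair: dict[tuple, list[RegionSpan]] = {}
    for r in regions:
        if r.protein_id != protein.id:
            raise ValueError(f"region {r.protein_id!r} does not belong to protein {protein.id!r}")
        by_pair.setdefault(r.pair, []).append(r)

    merged: list[RegionSpan] = []
    for pair, group in by_pair.items():
        group = sorted(group, key=lambda r: r.start)
        cur = group[0]
        for nxt in group[1:]:
            gap = nxt.start - cur.end - 1
            if gap <= merge_gap:
                cur = RegionSpan(
                    protein_id=protein.id,
                    start=cur.start,
                    end=nxt.end,
                    pair=pair,
                    sequence=protein.sequence[cur.start - 1 : nxt.end],
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)

    merged.sort(key=lambda r: (r.start, r.end, r.pair))
    return merged


def apply_filters(regions: Iterable, params: ScanParams) -> list:
    """Filter classified regions by pair, category and minimum unit count.

    Operates on :class:`~polyxy.classify.PolyXYRegion` objects (regions that
    already carry a category).  With ``min_units`` set, non-direpeats are
    dropped.
    """
    out = []
    for r in regions:
        if params.pair_filter is not None:
            x, y = params.pair_filter
            if x is None:
                if y not in r.pair:
                    continue
            elif tuple(sorted((x, y))) != r.pair:
                continue
        if params.category_filter is not None and r.category not in params.category_filter:
            continue
        if params.min_units is not None:
            if r.category != "direpeat" or r.n_units < params.min_units:
                continue
        out.append(r)
    return out
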
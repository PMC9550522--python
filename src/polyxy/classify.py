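"""Categorization of polyXY regions: direpeat, joined or shuffled.

Direpeats are perfect short tandem repeats of the two-residue unit 'XY'
(equivalently 'YX'), tolerating at most one lone X or Y anywhere in the
region (at a terminus or between units).  Joined regions are a run of X
immediately followed by a run of Y, each run of length >= 2; the order
X-then-Y is biologically meaningful and recorded.  Everything else is
shuffled.  The categories are mutually exclusive and exhaustive; direpeat
is tested first, then joined.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Optional, Sequence

from .detect import RegionSpan

__all__ = [
    "PolyXYRegion",
    "CATEGORIES",
    "classify_region",
    "count_direpeat_units",
    "find_embedded_patterns",
    "classify_all",
    "is_direpeat",
    "joined_order",
]

CATEGORIES = ("direpeat", "joined", "shuffled")


@dataclass(frozen=True)
class PolyXYRegion:
    """A classified polyXY region.

    ``n_units`` is set for direpeats only (number of complete 'XY' units;
    a lone residue does not count).  ``joined_order`` is set for joined
    regions only, as the 2-tuple (first-run residue, second-run residue).
    ``contains_joined`` / ``contains_direpeat`` are set for shuffled
    regions once :func:`find_embedded_patterns` has been applied.
    """

    protein_id: str
    start: int
    end: int
    pair: tuple
    sequence: str
    category: str
    n_units: Optional[int] = None
    joined_order: Optional[tuple] = None
    contains_joined: Optional[bool] = None
    contains_direpeat: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "direpeat") != (self.n_units is not None):
            raise ValueError("n_units is set iff category is direpeat")
        if (self.category == "joined") != (self.joined_order is not None):
            raise ValueError("joined_order is set iff category is joined")

    def __len__(self) -> int:
        return self.end - self.start + 1


def _runs(seq: str) -> list[tuple[str, int]]:
    return [(ch, sum(1 for _ in grp)) for ch, grp in groupby(seq)]


def is_direpeat(seq: str) -> bool:
    """True iff ``seq`` is units 'XY' (or 'YX') with at most one lone residue.

    Equivalently: ``seq`` equals some ``u * k`` for ``u`` in {XY, YX}
    (even length), or becomes one after removing a single residue (odd
    length).  The lone residue may sit at a terminus or between units.
    """
    letters = sorted(set(seq))
    if len(letters) != 2:
        return False
    x, y = letters
    n = len(seq)
    if n % 2 == 0:
        return _is_perfect(seq, x, y)
    return any(_is_perfect(seq[:i] + seq[i + 1 :], x, y) for i in range(n))


def _is_perfect(seq: str, x: str, y: str) -> bool:
    k = len(seq) // 2
    return seq == (x + y) * k or seq == (y + x) * k


def joined_order(seq: str) -> Optional[tuple]:
    """Return (X, Y) if ``seq`` is polyX followed by polyY (runs >= 2), else None."""
    runs = _runs(seq)
    if len(runs) == 2 and runs[0][1] >= 2 and runs[1][1] >= 2:
        return (runs[0][0], runs[1][0])
    return None


def classify_region(region: RegionSpan) -> PolyXYRegion:
    """Assign the region to exactly one category.

    Precedence: direpeat, then joined, then shuffled.  A merged region
    (``merge_gap`` > 0), whose sequence contains residues outside its
    pair, is always shuffled: the interrupting residues break both the
    unit coverage and the two-run structure.
    """
    seq = region.sequence
    category = "shuffled"
    n_units: Optional[int] = None
    order: Optional[tuple] = None
    if set(seq) == set(region.pair):
        if is_direpeat(seq):
            category = "direpeat"
            n_units = len(seq) // 2
        else:
            order = joined_order(seq)
            if order is not None:
                category = "joined"
    return PolyXYRegion(
        protein_id=region.protein_id,
        start=region.start,
        end=region.end,
        pair=region.pair,
        sequence=seq,
        category=category,
        n_units=n_units,
        joined_order=order,
    )


def count_direpeat_units(region_sequence: str, pair: tuple) -> int:
    """Number of complete 2-residue units in a direpeat sequence.

    The single allowed lone residue does not count as a unit, so the
    result is ``len(seq) // 2``.  Calling this on a non-direpeat is a
    contract violation.
    """
    if set(region_sequence) != set(pair):
        raise ValueError("sequence letters do not match the pair")
    if not is_direpeat(region_sequence):
        raise ValueError(f"{region_sequence!r} is not a direpeat")
    return len(region_sequence) // 2


def find_embedded_patterns(region: PolyXYRegion, window: int = 6) -> tuple[bool, bool]:
    """Search a shuffled region for embedded joined / direpeat sub-spans.

    Returns ``(contains_joined, contains_direpeat)``: whether some
    sub-span of length >= ``window`` satisfies the joined (two runs, each
    >= 2) or the direpeat definition (including the one-lone-residue
    allowance).  Both may be true.
    """
    if region.category != "shuffled":
        raise ValueError("find_embedded_patterns applies to shuffled regions only")
    seq = region.sequence
    runs = _runs(seq)
    # A joined sub-span is a suffix of one maximal run (>= 2) followed by a
    # prefix of the next (>= 2), so only adjacent run pairs need checking.
    found_joined = any(
        runs[t][1] >= 2 and runs[t + 1][1] >= 2 and runs[t][1] + runs[t + 1][1] >= window
        for t in range(len(runs) - 1)
    )
    return found_joined, _contains_direpeat(seq, runs, window)


def _contains_direpeat(seq: str, runs: list, window: int) -> bool:
    """True iff some sub-span of length >= window satisfies the direpeat rule.

    A direpeat sub-span uses exactly two letters, so it lies inside a
    maximal stretch of consecutive runs over two letter values; each such
    stretch is examined with an alternation/defect analysis instead of
    enumerating sub-spans.
    """
    n_runs = len(runs)
    t = 0
    while t < n_runs:
        if t + 1 >= n_runs:
            break  # a single trailing run cannot hold two letter types
        a, b = runs[t][0], runs[t + 1][0]
        t2 = t + 2
        while t2 < n_runs and runs[t2][0] in (a, b):
            t2 += 1
        stretch = "".join(ch * cnt for ch, cnt in runs[t:t2])
        if _two_letter_contains_direpeat(stretch, window):
            return True
        t = max(t2 - 1, t + 1)  # the breaking run may pair with its predecessor
    return False


def _two_letter_contains_direpeat(s: str, window: int) -> bool:
    # Lengths of maximal alternating blocks (split at each pair of equal
    # adjacent residues).  An alternating sub-span of length >= window is a
    # direpeat (even length: perfect units; odd: one terminal lone residue).
    # A sub-span crossing exactly one defect is a direpeat iff its length is
    # odd (removing one residue of the defect restores perfect alternation),
    # which is achievable iff the two flanking blocks jointly reach the
    # smallest odd length >= window.
    blocks = []
    cur = 1
    for i in range(1, len(s)):
        if s[i] == s[i - 1]:
            blocks.append(cur)
            cur = 1
        else:
            cur += 1
    blocks.append(cur)
    if max(blocks) >= window:
        return True
    odd_need = window if window % 2 else window + 1
    return any(blocks[i] + blocks[i + 1] >= odd_need for i in range(len(blocks) - 1))


def classify_all(regions: Sequence[RegionSpan], window: int = 6) -> list[PolyXYRegion]:
    """Classify every region and annotate shuffled ones with embedded patterns."""
    out = []
    for region in regions:
        classified = classify_region(region)
        if classified.category == "shuffled":
            cj, cd = find_embedded_patterns(classified, window=window)
            classified = PolyXYRegion(
                protein_id=classified.protein_id,
                start=classified.start,
                end=classified.end,
                pair=classified.pair,
                sequence=classified.sequence,
                category="shuffled",
                contains_joined=cj,
                contains_direpeat=cd,
            )
        out.append(classified)
    return out
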
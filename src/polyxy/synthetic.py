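"""Synthetic proteomes with planted polyXY regions of known ground truth.

The generator draws background residues from a configurable amino-acid
distribution (default: average composition of well-curated protein
databases) and splices in planted regions of a requested pair, category
and length, guarded on each side by two residues outside the plant's pair
so the planted span cannot silently extend.

Truth is defined *by oracle*, not by intent: the emitted truth table is
the output of an independent brute-force scanner on the final sequences,
so polyXY regions formed accidentally by the background are part of the
truth rather than a source of flaky comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .classify import PolyXYRegion, classify_region, is_direpeat, joined_order
from .detect import STANDARD_AA, ProteinRecord, RegionSpan
from .io import AnnotationInterval, write_annotations, write_fasta, write_regions_tsv

__all__ = [
    "Plant",
    "AnnotationPlan",
    "FixtureSpec",
    "Fixture",
    "generate_fixture",
    "write_fixture",
    "brute_force_regions",
    "DEFAULT_BACKGROUND",
]

#: Average amino-acid composition (fractions) of curated protein sequence
#: databases, used as the default background distribution.
DEFAULT_BACKGROUND = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0672, "G": 0.0707, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0664, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}
_total = sum(DEFAULT_BACKGROUND.values())
DEFAULT_BACKGROUND = {k: v / _total for k, v in DEFAULT_BACKGROUND.items()}


# ---------------------------------------------------------------------------
# Brute-force reference scanner (the oracle that defines fixture truth)
# ---------------------------------------------------------------------------

def _window_pair(window_seq: str) -> Optional[tuple]:
    """Plain re-statement of the window test, kept separate from detect()."""
    kinds = set(window_seq)
    if len(kinds) != 2 or not kinds <= STANDARD_AA:
        return None
    a, b = sorted(kinds)
    if window_seq.count(a) >= 2 and window_seq.count(b) >= 2:
        return (a, b)
    return None


def brute_force_regions(protein: ProteinRecord, window: int = 6) -> list[RegionSpan]:
    """Reference polyXY scanner: enumerate every window, test it, and merge
    overlapping same-pair positives to a fixpoint by repeated pairwise union.

    Deliberately naive (quadratic merging) so it shares no code path with
    :func:`polyxy.detect.detect_regions`; used to define fixture truth and
    as the comparison oracle in the test-suite.
    """
    seq = protein.sequence
    intervals = []  # (start0, end0, pair), inclusive 0-based
    for i in range(len(seq) - window + 1):
        pair = _window_pair(seq[i : i + window])
        if pair is not None:
            intervals.append((i, i + window - 1, pair))

    changed = True
    while changed:
        changed = False
        i = 0
        while i < len(intervals):
            j = i + 1
            while j < len(intervals):
                s1, e1, p1 = intervals[i]
                s2, e2, p2 = intervals[j]
                if p1 == p2 and s2 <= e1 and s1 <= e2:  # share >= 1 position
                    intervals[i] = (min(s1, s2), max(e1, e2), p1)
                    del intervals[j]
                    changed = True
                else:
                    j += 1
            i += 1

    regions = [
        RegionSpan(
            protein_id=protein.id,
            start=s + 1,
            end=e + 1,
            pair=p,
            sequence=seq[s : e + 1],
        )
        for s, e, p in intervals
    ]
    regions.sort(key=lambda r: (r.start, r.end, r.pair))
    return regions


# ---------------------------------------------------------------------------
# Fixture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plant:
    """One planted polyXY region.

    ``length`` must be >= the scan window; for joined plants the first run
    takes ``ceil(length / 2)`` residues of ``joined_order[0]`` unless
    ``split`` overrides the first-run length.
    """

    pair: tuple
    category: str
    length: int
    joined_order: Optional[tuple] = None
    split: Optional[int] = None

    def __post_init__(self) -> None:
        if self.category not in ("direpeat", "joined", "shuffled"):
            raise ValueError(f"unknown plant category {self.category!r}")
        x, y = self.pair
        if x == y or not {x, y} <= STANDARD_AA:
            raise ValueError(f"plant pair must be two distinct standard residues, got {self.pair!r}")
        if tuple(sorted(self.pair)) != tuple(self.pair):
            object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        if self.category == "joined":
            order = self.joined_order or self.pair
            if set(order) != set(self.pair):
                raise ValueError("joined_order letters must equal the pair")
            object.__setattr__(self, "joined_order", tuple(order))
        elif self.joined_order is not None:
            raise ValueError("joined_order is only meaningful for joined plants")

    def build(self, rng: np.random.Generator, window: int) -> str:
        if self.length < window:
            raise ValueError(f"plant length {self.length} below window {window}")
        x, y = self.pair
        if self.category == "direpeat":
            return ((x + y) * self.length)[: self.length]
        if self.category == "joined":
            first, second = self.joined_order
            a = self.split if self.split is not None else (self.length + 1) // 2
            if not (2 <= a <= self.length - 2):
                raise ValueError("joined plant runs must both be >= 2")
            return first * a + second * (self.length - a)
        # Shuffled: rejection-sample a two-letter string in which every
        # window is positive (so the plant is one region) and which is
        # neither a direpeat nor joined.
        for _ in range(1000):
            seq = "".join(rng.choice([x, y], size=self.length))
            if _window_pair(seq[:window]) is None:
                continue
            if any(_window_pair(seq[i : i + window]) is None for i in range(1, self.length - window + 1)):
                continue
            if is_direpeat(seq) or joined_order(seq) is not None:
                continue
            return seq
        raise RuntimeError("could not sample a shuffled plant (length too small?)")


@dataclass(frozen=True)
class AnnotationPlan:
    """Rules placing annotation intervals relative to plants.

    ``cover_plants_with`` wraps every planted span in an interval of the
    given kind, padded by ``pad`` residues on each side (clipped to the
    protein).  ``n_random_domains`` extra domain intervals of length
    ``random_domain_length`` are placed uniformly at random per protein.
    """

    cover_plants_with: Optional[str] = "disorder"
    pad: int = 3
    n_random_domains: int = 0
    random_domain_length: int = 50

    def __post_init__(self) -> None:
        if self.cover_plants_with not in (None, "domain", "disorder"):
            raise ValueError(f"cover_plants_with must be None, 'domain' or 'disorder'")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic proteome fixture."""

    n_proteins: int = 20
    length_range: tuple = (80, 400)
    background_frequencies: Optional[dict] = None
    plants: tuple = ()
    annotation_plan: Optional[AnnotationPlan] = None
    window: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        if not (self.window <= lo <= hi):
            raise ValueError(f"length_range must satisfy window <= lo <= hi, got {self.length_range}")
        freqs = self.background_frequencies or DEFAULT_BACKGROUND
        if set(freqs) - STANDARD_AA:
            raise ValueError("background frequencies must be over standard amino acids")
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"background frequencies must sum to 1, got {total}")
        object.__setattr__(self, "background_frequencies", dict(freqs))
        object.__setattr__(self, "plants", tuple(self.plants))
        for plant in self.plants:
            if plant.length < self.window:
                raise ValueError(f"plant length {plant.length} below window {self.window}")
            if plant.length > hi:
                raise ValueError(f"plant length {plant.length} exceeds longest protein ({hi})")


@dataclass(frozen=True)
class Fixture:
    proteins: tuple
    truth: tuple  # classified PolyXYRegion, oracle-defined
    annotations: tuple


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Generate proteins, an oracle-defined truth table, and annotations."""
    rng = np.random.default_rng(spec.seed)
    letters = sorted(spec.background_frequencies)
    probs = np.array([spec.background_frequencies[a] for a in letters])
    probs = probs / probs.sum()

    lo, hi = spec.length_range
    proteins: list[ProteinRecord] = []
    planted_spans: dict[str, list[tuple[int, int]]] = {}
    for idx in range(spec.n_proteins):
        pid = f"SYN{idx + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        plants = [p for j, p in enumerate(spec.plants) if j % spec.n_proteins == idx]
        for plant in plants:
            insert = plant.build(rng, spec.window)
            guard_pool = sorted(STANDARD_AA - set(plant.pair))
            guards_left = "".join(rng.choice(guard_pool, size=2))
            guards_right = "".join(rng.choice(guard_pool, size=2))
            block = guards_left + insert + guards_right
            cut = int(rng.integers(0, len(seq) + 1))
            start = cut + len(guards_left) + 1  # 1-based start of the plant
            seq = seq[:cut] + block + seq[cut:]
            planted_spans.setdefault(pid, []).append((start, start + plant.length - 1))
        proteins.append(ProteinRecord(id=pid, sequence=seq))

    truth: list[PolyXYRegion] = []
    for protein in proteins:
        for region in brute_force_regions(protein, window=spec.window):
            truth.append(classify_region(region))

    annotations: list[AnnotationInterval] = []
    plan = spec.annotation_plan
    if plan is not None:
        for protein in proteins:
            if plan.cover_plants_with is not None:
                for start, end in planted_spans.get(protein.id, []):
                    annotations.append(
                        AnnotationInterval(
                            protein_id=protein.id,
                            start=max(1, start - plan.pad),
                            end=min(len(protein), end + plan.pad),
                            kind=plan.cover_plants_with,
                            name="planted",
                        )
                    )
            for _ in range(plan.n_random_domains):
                m = min(plan.random_domain_length, len(protein))
                s = int(rng.integers(1, len(protein) - m + 2))
                annotations.append(
                    AnnotationInterval(
                        protein_id=protein.id, start=s, end=s + m - 1, kind="domain", name="random"
                    )
                )

    return Fixture(proteins=tuple(proteins), truth=tuple(truth), annotations=tuple(annotations))


def write_fixture(fixture: Fixture, out_dir: Union[str, Path]) -> dict:
    """Write proteins.fasta, truth_regions.tsv and annotations.tsv; return paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out_dir / "proteins.fasta",
        "truth": out_dir / "truth_regions.tsv",
        "annotations": out_dir / "annotations.tsv",
    }
    write_fasta(fixture.proteins, paths["fasta"])
    write_regions_tsv(list(fixture.truth), paths["truth"])
    write_annotations(list(fixture.annotations), paths["annotations"])
    return paths
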
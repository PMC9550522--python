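"""File formats: FASTA in, region/annotation/summary TSV in and out.

All coordinates in files are 1-based and inclusive on both ends.  TSV
files are tab-separated, unquoted, with a header line and Unix line
endings; both Unix and Windows endings are accepted on input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

from .classify import PolyXYRegion
from .detect import ProteinRecord

__all__ = [
    "AnnotationInterval",
    "read_fasta",
    "write_fasta",
    "write_regions_tsv",
    "read_regions_tsv",
    "read_annotations",
    "write_annotations",
    "REGION_COLUMNS",
]

ANNOTATION_KINDS = ("domain", "disorder")

REGION_COLUMNS = (
    "protein_id",
    "start",
    "end",
    "pair",
    "sequence",
    "category",
    "n_units",
    "joined_order",
)


@dataclass(frozen=True)
class AnnotationInterval:
    """A labeled span on a protein: a globular domain or a predicted IDR."""

    protein_id: str
    start: int
    end: int
    kind: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid annotation span {self.start}-{self.end}")
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"annotation kind must be one of {ANNOTATION_KINDS}, got {self.kind!r}")


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Ids are the first whitespace-delimited header tokens; duplicate ids are
    a hard error (downstream per-protein statistics would silently
    double-count).  Sequences are upper-cased; wrapped lines are
    concatenated.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(f"{path}: not FASTA (line {lineno} does not start with '>')")
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    """Write proteins as wrapped FASTA."""
    with open(path, "w", newline="\n") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_regions_tsv(regions: Sequence[PolyXYRegion], path: Union[str, Path]) -> None:
    """Write classified regions as TSV (header + one row per region).

    Columns: protein_id, start, end, pair (two letters, alphabetical),
    sequence, category, n_units (empty unless direpeat), joined_order
    (two letters in sequence order, empty unless joined).
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            row = (
                r.protein_id,
                str(r.start),
                str(r.end),
                "".join(r.pair),
                r.sequence,
                r.category,
                "" if r.n_units is None else str(r.n_units),
                "" if r.joined_order is None else "".join(r.joined_order),
            )
            fh.write("\t".join(row) + "\n")


def read_regions_tsv(path: Union[str, Path]) -> list[PolyXYRegion]:
    """Read a region TSV written by :func:`write_regions_tsv`."""
    path = Path(path)
    regions: list[PolyXYRegion] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty regions file") from None
        if tuple(header) != REGION_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for rowno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(REGION_COLUMNS):
                raise ValueError(f"{path}: row {rowno}: expected {len(REGION_COLUMNS)} fields")
            pid, start, end, pair, seq, category, n_units, order = row
            try:
                regions.append(
                    PolyXYRegion(
                        protein_id=pid,
                        start=int(start),
                        end=int(end),
                        pair=tuple(pair),
                        sequence=seq,
                        category=category,
                        n_units=int(n_units) if n_units else None,
                        joined_order=tuple(order) if order else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from None
    return regions


def read_annotations(path: Union[str, Path]) -> list[AnnotationInterval]:
    """Read annotation intervals from a TSV.

    Columns: protein_id, start, end, kind ('domain' or 'disorder'), name.
    A header line starting with 'protein_id' is accepted and skipped, so
    both headered and bare files work.
    """
    path = Path(path)
    intervals: list[AnnotationInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rowno, row in enumerate(reader, start=1):
            if not row or (rowno == 1 and row[0] == "protein_id"):
                continue
            if len(row) < 4:
                raise ValueError(f"{path}: row {rowno}: expected at least 4 fields, got {len(row)}")
            pid, start, end, kind = row[:4]
            name = row[4] if len(row) > 4 else ""
            try:
                intervals.append(
                    AnnotationInterval(protein_id=pid, start=int(start), end=int(end), kind=kind, name=name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from None
    return intervals


def write_annotations(intervals: Sequence[AnnotationInterval], path: Union[str, Path]) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("protein_id\tstart\tend\tkind\tname\n")
        for iv in intervals:
            fh.write(f"{iv.protein_id}\t{iv.start}\t{iv.end}\t{iv.kind}\t{iv.name}\n")
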
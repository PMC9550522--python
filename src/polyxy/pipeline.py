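"""High-level scan pipeline: detect, merge, classify, filter."""

from __future__ import annotations

from typing import Sequence

from .classify import PolyXYRegion, classify_all
from .detect import ProteinRecord, ScanParams, apply_filters, detect_regions, merge_close_regions

__all__ = ["scan_protein", "scan_proteins"]


def scan_protein(
    protein: ProteinRecord, params: ScanParams = ScanParams(), embedded: bool = False
) -> list[PolyXYRegion]:
    """Detect, optionally gap-merge, classify and filter regions of one protein.

    With ``embedded=True``, shuffled regions are additionally annotated
    with their embedded joined/direpeat flags.
    """
    regions = detect_regions(protein, params)
    if params.merge_gap > 0 and regions:
        regions = merge_close_regions(regions, protein, params.merge_gap)
    if embedded:
        classified = classify_all(regions, window=params.window)
    else:
        from .classify import classify_region

        classified = [classify_region(r) for r in regions]
    if params.pair_filter or params.category_filter or params.min_units:
        classified = apply_filters(classified, params)
    return classified


def scan_proteins(
    proteins: Sequence[ProteinRecord], params: ScanParams = ScanParams(), embedded: bool = False
) -> list[PolyXYRegion]:
    """Scan many proteins; regions are grouped by protein in input order."""
    out: list[PolyXYRegion] = []
    for protein in proteins:
        out.extend(scan_protein(protein, params, embedded=embedded))
    return out
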
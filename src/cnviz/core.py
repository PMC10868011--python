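"""Numeric core: log2 transform, gain/loss classification, region queries,
genome layout arithmetic and zoom."""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right

from .model import (
    CnvizError,
    CNState,
    CopyNumberWindow,
    Gene,
    GeneCatalog,
    GenomeCopyNumber,
    ViewRegion,
    chrom_sort_key,
    normalize_chrom,
)

__all__ = [
    "log2_ratio",
    "classify_state",
    "genome_offsets",
    "find_gene",
    "genes_in_region",
    "windows_in_region",
    "apply_zoom",
    "ZOOM_FACTORS",
]

#: Permitted zoom factors; positive = zoom in, negative = zoom out.
ZOOM_FACTORS = (2, 10, -2, -10)


def log2_ratio(copy_number: float, ploidy: int) -> float:
    """log2 copy-number ratio relative to the baseline ploidy.

    log2(copy_number / ploidy): 0 at the ploidy, -1 for a single copy at
    ploidy 2, +1 for four copies at ploidy 2.  A copy number of zero maps to
    -inf; the renderer clamps it to a finite floor.
    """
    if ploidy <= 0:
        raise CnvizError(f"ploidy must be positive, got {ploidy}")
    if copy_number < 0:
        raise CnvizError(f"copy number must be >= 0, got {copy_number}")
    if copy_number == 0:
        return float("-inf")
    return math.log2(copy_number / ploidy)


def classify_state(copy_number: int, ploidy: int) -> CNState:
    """Gain above ploidy, loss below, neutral at equality."""
    if copy_number > ploidy:
        return CNState.GAIN
    if copy_number < ploidy:
        return CNState.LOSS
    return CNState.NEUTRAL


def genome_offsets(sizes: list[tuple[str, int]]) -> dict[str, int]:
    """Cumulative base-pair offset of each chromosome on a concatenated axis.

    The first chromosome starts at 0; each subsequent offset is the previous
    offset plus the previous chromosome's size.
    """
    offsets: dict[str, int] = {}
    pos = 0
    for name, size in sizes:
        if name in offsets:
            raise CnvizError(f"duplicate chromosome {name!r} in size list")
        if size <= 0:
            raise CnvizError(f"chromosome {name!r} has non-positive size {size}")
        offsets[name] = pos
        pos += size
    return offsets


def find_gene(catalog: GeneCatalog, name: str) -> list[Gene]:
    """All loci matching a gene name, case-insensitively, in chromosome order."""
    hits = catalog.name_index.get(name.strip().upper(), [])
    return sorted(hits, key=lambda g: (chrom_sort_key(g.chromosome), g.start))


def _require_chromosome_scoped(region: ViewRegion) -> str:
    from .model import WHOLE_GENOME

    if region.chromosome == WHOLE_GENOME:
        raise CnvizError("region query requires a chromosome-scoped region")
    return region.chromosome


def genes_in_region(catalog: GeneCatalog, region: ViewRegion) -> list[Gene]:
    """Genes whose [start, end) overlaps the region, ordered by start.

    Overlap is half-open: a gene ending exactly at region.start (or starting
    at region.end) does not overlap.
    """
    chrom = _require_chromosome_scoped(region)
    if chrom not in catalog.genes:
        raise CnvizError(f"unknown chromosome {chrom!r} in gene catalog")
    genes = catalog.genes[chrom]
    starts = [g.start for g in genes]
    # candidates: genes starting before region.end; filter on end > start
    hi = bisect_left(starts, region.end)
    return [g for g in genes[:hi] if g.end > region.start]


def windows_in_region(
    genome: GenomeCopyNumber, region: ViewRegion
) -> list[CopyNumberWindow]:
    """Non-missing windows whose [start, start+window_size) overlaps the region."""
    chrom = _require_chromosome_scoped(region)
    if chrom not in genome.windows:
        raise CnvizError(f"unknown chromosome {chrom!r} in copy-number data")
    ws = genome.window_size or 1
    windows = genome.windows[chrom]
    starts = [w.start for w in windows]
    lo = bisect_right(starts, region.start - ws)
    hi = bisect_left(starts, region.end)
    return [
        w
        for w in windows[lo:hi]
        if w.state is not CNState.MISSING and w.start + ws > region.start
    ]


def apply_zoom(
    region: ViewRegion,
    factor: int,
    anchor: float | None = None,
    chromosome_size: int | None = None,
) -> ViewRegion:
    """Zoom a chromosome-scoped region in (factor 2 or 10) or out (-2 or -10).

    Zoom-in divides the span by the factor, centered on the anchor (default:
    region midpoint).  Zoom-out multiplies it.  The result is clamped to
    [0, chromosome_size]; when clamping hits an edge the span is preserved by
    shifting, and a span exceeding the chromosome yields the full chromosome.
    """
    chrom = _require_chromosome_scoped(region)
    if factor not in ZOOM_FACTORS:
        raise CnvizError(
            f"zoom factor must be one of {ZOOM_FACTORS}, got {factor}"
        )
    span = region.span
    if factor > 0:
        new_span = max(1, round(span / factor))
        if anchor is None:
            anchor = (region.start + region.end) / 2
        elif not (region.start <= anchor <= region.end):
            raise CnvizError("zoom-in anchor must lie within the region")
    else:
        new_span = span * (-factor)
        if anchor is None:
            anchor = (region.start + region.end) / 2

    start = round(anchor - new_span / 2)
    end = start + new_span

    limit = chromosome_size
    if limit is not None and new_span >= limit:
        return ViewRegion(chrom, 0, limit)
    if start < 0:
        start, end = 0, new_span
    if limit is not None and end > limit:
        start, end = limit - new_span, limit
    return ViewRegion(chrom, start, end)
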
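"""In-memory model for copy-number windows, gene annotation and ideograms.

All coordinates are stored 0-based half-open, regardless of the on-disk
convention of the source format (GTF is 1-based inclusive, bam_ratio starts
are 1-based, UCSC cytoBand is already 0-based half-open).  Chromosome names
are normalized by stripping a leading ``chr`` prefix so that Control-FREEC
output and UCSC annotation interoperate; the prefix is re-added for display.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "CnvizError",
    "FormatError",
    "CNState",
    "GiemsaStain",
    "STAIN_COLORS",
    "CopyNumberWindow",
    "GenomeCopyNumber",
    "Gene",
    "GeneCatalog",
    "CytoBandSegment",
    "CytoBandSet",
    "StyleConfig",
    "ViewRegion",
    "WHOLE_GENOME",
    "ReferenceRegistry",
    "normalize_chrom",
    "display_chrom",
    "chrom_sort_key",
    "sort_chromosomes",
    "valid_chromosome_set",
    "chromosome_sizes",
]


class CnvizError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CnvizError):
    """An input file violates its format contract."""


# ---------------------------------------------------------------------------
# chromosome naming
# ---------------------------------------------------------------------------

def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name.

    ``"chr2"`` and ``"2"`` normalize to the same key so the three input files
    can disagree on the prefix without consequence.
    """
    name = name.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


def display_chrom(name: str) -> str:
    """Render a normalized chromosome name with the conventional prefix."""
    return name if name.lower().startswith("chr") else "chr" + name


def chrom_sort_key(name: str):
    """Natural chromosome ordering: 1..n numeric, then X, Y, M/MT, then others."""
    n = normalize_chrom(name)
    if n.isdigit():
        return (0, int(n), "")
    u = n.upper()
    if u == "X":
        return (1, 0, "")
    if u == "Y":
        return (2, 0, "")
    if u in ("M", "MT"):
        return (3, 0, "")
    return (4, 0, n)


def sort_chromosomes(names: Iterable[str]) -> list[str]:
    return sorted(names, key=chrom_sort_key)


# ---------------------------------------------------------------------------
# copy-number windows
# ---------------------------------------------------------------------------

class CNState(str, Enum):
    """Classification of a window relative to the genome ploidy."""

    GAIN = "gain"
    LOSS = "loss"
    NEUTRAL = "neutral"
    MISSING = "missing"


@dataclass(slots=True)
class CopyNumberWindow:
    """One genomic window of a copy-number profile.

    ``log2_ratio`` is the log2 copy-number ratio of the window
    (0 at the baseline ploidy, -1 for a single copy at ploidy 2);
    ``segment_median_log2`` is the log2 of the median ratio of the segment
    the window belongs to, which drives the aggregation line.
    ``state`` is MISSING iff the source row carried the -1 sentinel.
    """

    chromosome: str
    start: int
    log2_ratio: float
    segment_median_log2: float
    copy_number: int
    state: CNState

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"window start must be >= 0, got {self.start}")


@dataclass
class GenomeCopyNumber:
    """Per-chromosome ordered lists of copy-number windows.

    Windows are keyed by normalized chromosome name; each list is strictly
    ascending by start.  ``window_size`` is the inferred span of one window
    (mode of consecutive start differences).
    """

    windows: dict[str, list[CopyNumberWindow]] = field(default_factory=dict)
    ploidy: int = 2
    window_size: int = 0
    source_path: str = ""

    def chromosomes(self) -> list[str]:
        return sort_chromosomes(self.windows)

    def n_windows(self, include_missing: bool = False) -> int:
        if include_missing:
            return sum(len(ws) for ws in self.windows.values())
        return sum(
            1
            for ws in self.windows.values()
            for w in ws
            if w.state is not CNState.MISSING
        )

    def validate(self) -> None:
        for chrom, ws in self.windows.items():
            starts = [w.start for w in ws]
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise ValueError(f"windows on {chrom} not strictly ascending")


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class Gene:
    """A gene locus with its exon intervals (all 0-based half-open)."""

    name: str
    chromosome: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.name}: start must be < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"gene {self.name}: exon [{s},{e}) outside gene span"
                )
        self.exons.sort()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class GeneCatalog:
    """Genes grouped per chromosome plus a case-insensitive name index."""

    genes: dict[str, list[Gene]] = field(default_factory=dict)
    name_index: dict[str, list[Gene]] = field(default_factory=dict)

    @classmethod
    def from_genes(cls, genes: Iterable[Gene]) -> "GeneCatalog":
        by_chrom: dict[str, list[Gene]] = {}
        index: dict[str, list[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
            index.setdefault(g.name.upper(), []).append(g)
        for lst in by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))
        for lst in index.values():
            lst.sort(key=lambda g: (chrom_sort_key(g.chromosome), g.start))
        return cls(genes=by_chrom, name_index=index)

    @property
    def valid_chromosomes(self) -> set[str]:
        return set(self.genes)

    def n_genes(self) -> int:
        return sum(len(gs) for gs in self.genes.values())


def valid_chromosome_set(catalog: GeneCatalog) -> set[str]:
    """The set of chromosome names carrying at least one annotated gene.

    This is the filter applied to bam_ratio rows at load time: windows on
    chromosomes outside this set are discarded.
    """
    return catalog.valid_chromosomes


# ---------------------------------------------------------------------------
# cytobands
# ---------------------------------------------------------------------------

class GiemsaStain(str, Enum):
    """The eight Giemsa staining classes of the UCSC cytoBand vocabulary."""

    GNEG = "gneg"
    GPOS25 = "gpos25"
    GPOS50 = "gpos50"
    GPOS75 = "gpos75"
    GPOS100 = "gpos100"
    ACEN = "acen"
    GVAR = "gvar"
    STALK = "stalk"


RGB = tuple[int, int, int]

#: Constant stain -> 24-bit RGB mapping used by the ideogram renderer.
STAIN_COLORS: dict[GiemsaStain, RGB] = {
    GiemsaStain.GNEG: (255, 255, 255),
    GiemsaStain.GPOS25: (191, 191, 191),
    GiemsaStain.GPOS50: (128, 128, 128),
    GiemsaStain.GPOS75: (64, 64, 64),
    GiemsaStain.GPOS100: (0, 0, 0),
    GiemsaStain.ACEN: (139, 0, 0),
    GiemsaStain.GVAR: (224, 224, 224),
    GiemsaStain.STALK: (176, 196, 222),
}


@dataclass(slots=True)
class CytoBandSegment:
    """One cytogenetic band (0-based half-open, UCSC convention)."""

    chromosome: str
    start: int
    end: int
    band_name: str
    stain: GiemsaStain

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"band {self.band_name} on {self.chromosome}: start must be < end"
            )


@dataclass
class CytoBandSet:
    """Ideogram bands per chromosome, chromosome sizes, stain colors."""

    segments: dict[str, list[CytoBandSegment]] = field(default_factory=dict)
    chromosome_sizes: list[tuple[str, int]] = field(default_factory=list)
    stain_colors: dict[GiemsaStain, RGB] = field(
        default_factory=lambda: dict(STAIN_COLORS)
    )

    def size_of(self, chromosome: str) -> int:
        chromosome = normalize_chrom(chromosome)
        for name, size in self.chromosome_sizes:
            if name == chromosome:
                return size
        raise KeyError(f"no registered size for chromosome {chromosome!r}")

    def validate(self) -> None:
        for chrom, segs in self.segments.items():
            prev_end = 0
            for seg in segs:
                if seg.start < prev_end and prev_end > 0:
                    raise ValueError(f"overlapping bands on {chrom}")
                prev_end = seg.end
        for stain in GiemsaStain:
            if stain not in self.stain_colors:
                raise ValueError(f"stain_colors missing {stain.value}")


def chromosome_sizes(
    cytobands: CytoBandSet, catalog: GeneCatalog
) -> list[tuple[str, int]]:
    """Chromosome sizes in natural order, merged over bands and genes.

    The size of each chromosome is the larger of its last cytoband end and
    its last gene end, so a gene annotated past the banded region still fits
    on the plotted axis.  Chromosomes present only in the cytoband file are
    dropped; a catalog chromosome with no bands is an error.
    """
    sizes: list[tuple[str, int]] = []
    for chrom in sort_chromosomes(catalog.valid_chromosomes):
        if chrom not in cytobands.segments:
            raise CnvizError(
                f"chromosome {chrom!r} has genes but no cytoband annotation"
            )
        band_max = max(seg.end for seg in cytobands.segments[chrom])
        gene_max = max(g.end for g in catalog.genes[chrom])
        sizes.append((chrom, max(band_max, gene_max)))
    return sizes


# ---------------------------------------------------------------------------
# style
# ---------------------------------------------------------------------------

def _check_rgb(name: str, value) -> RGB:
    try:
        r, g, b = value
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be an (r, g, b) triple, got {value!r}")
    for c in (r, g, b):
        if not isinstance(c, int) or not 0 <= c <= 255:
            raise ValueError(f"{name} components must be integers in 0..255")
    return (r, g, b)


DEFAULT_PALETTE: list[RGB] = [
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
    (174, 199, 232),
    (255, 187, 120),
]


@dataclass
class StyleConfig:
    """All persistable visual parameters of the viewer.

    marker_size is the marker diameter in points (default 3, as in the
    whole-view marker slider); marker_alpha is the opacity in [0, 1].
    """

    marker_size: float = 3.0
    marker_alpha: float = 0.8
    gain_color: RGB = (214, 39, 40)
    loss_color: RGB = (44, 160, 44)
    neutral_color: RGB = (105, 105, 105)
    chromosome_palette: list[RGB] = field(
        default_factory=lambda: list(DEFAULT_PALETTE)
    )
    ratio_chart_background: RGB = (255, 255, 255)
    whole_exome_chart_background: RGB = (245, 245, 245)
    aggregate_line_color: RGB = (0, 0, 0)
    aggregate_line_thickness: float = 1.5
    preset_name: str = "default"

    def validate(self) -> None:
        if not 0.0 <= self.marker_alpha <= 1.0:
            raise ValueError(
                f"marker_alpha must be in [0, 1], got {self.marker_alpha}"
            )
        if not self.aggregate_line_thickness > 0:
            raise ValueError("aggregate_line_thickness must be > 0")
        if not self.marker_size > 0:
            raise ValueError("marker_size must be > 0")
        for name in (
            "gain_color",
            "loss_color",
            "neutral_color",
            "ratio_chart_background",
            "whole_exome_chart_background",
            "aggregate_line_color",
        ):
            setattr(self, name, _check_rgb(name, getattr(self, name)))
        if not self.chromosome_palette:
            raise ValueError("chromosome_palette must be nonempty")
        self.chromosome_palette = [
            _check_rgb("chromosome_palette", c) for c in self.chromosome_palette
        ]


# ---------------------------------------------------------------------------
# regions and references
# ---------------------------------------------------------------------------

#: Sentinel chromosome name for a genome-wide view region.
WHOLE_GENOME = "*"


@dataclass(slots=True)
class ViewRegion:
    """A displayed genomic interval, chromosome-scoped or genome-wide."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.chromosome != WHOLE_GENOME:
            self.chromosome = normalize_chrom(self.chromosome)

    @property
    def span(self) -> int:
        return self.end - self.start


class ReferenceRegistry:
    """Registry of gtf/cytoband reference pairs.

    Four built-in identifiers (hg38, hg19, mm39, mm10) are always present;
    their file locators resolve only once the user supplies local paths.
    Custom references may be registered alongside.
    """

    BUILTIN_IDS: tuple[str, ...] = ("hg38", "hg19", "mm39", "mm10")

    def __init__(self) -> None:
        self._entries: dict[str, tuple[Optional[str], Optional[str]]] = {
            rid: (None, None) for rid in self.BUILTIN_IDS
        }

    def list_ids(self) -> list[str]:
        builtins = list(self.BUILTIN_IDS)
        customs = [rid for rid in self._entries if rid not in self.BUILTIN_IDS]
        return builtins + customs

    def register(self, rid: str, gtf: Optional[str], cytoband: Optional[str]) -> None:
        self._entries[rid] = (gtf, cytoband)

    def resolve(self, rid: str) -> tuple[str, str]:
        if rid not in self._entries:
            raise CnvizError(
                f"unknown reference {rid!r}; available: {', '.join(self.list_ids())}"
            )
        gtf, cyto = self._entries[rid]
        if gtf is None or cyto is None:
            raise CnvizError(
                f"reference {rid!r} is registered but its annotation paths are "
                "not configured; supply --gtf/--cytoband or a references config"
            )
        return gtf, cyto
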
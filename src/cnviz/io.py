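"""Readers for the three input formats (bam_ratio, GTF, cytoBand) and
persistence of the visual style configuration.

bam_ratio files are the tab-separated per-window output of Control-FREEC and
compatible callers: columns ``Chromosome``, ``Start``, ``Ratio``,
``MedianRatio``, ``CopyNumber`` (extra columns are ignored).  ``Ratio`` and
``MedianRatio`` are linear ratios on the copy-number/ploidy scale; they are
log2-transformed at load so that a diploid window plots at 0 and a single
copy at -1.  A ``Ratio`` of -1 is the caller's sentinel for windows it could
not assess; such windows are kept with state ``missing`` and excluded from
plots and statistics.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import math
import re
from collections import Counter
from dataclasses import asdict
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
import yaml

from .core import classify_state
from .model import (
    CNState,
    CopyNumberWindow,
    CytoBandSegment,
    CytoBandSet,
    FormatError,
    Gene,
    GeneCatalog,
    GenomeCopyNumber,
    GiemsaStain,
    StyleConfig,
    chrom_sort_key,
    display_chrom,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_bam_ratio",
    "read_gtf",
    "read_cytoband",
    "write_cytoband",
    "save_style",
    "load_style",
    "MISSING_SENTINEL",
]

#: Linear-ratio value Control-FREEC emits for unassessable windows.
MISSING_SENTINEL = -1.0

RATIO_COLUMNS = ("Chromosome", "Start", "Ratio", "MedianRatio", "CopyNumber")


# ---------------------------------------------------------------------------
# bam_ratio
# ---------------------------------------------------------------------------

def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    """Map required column names onto the dataframe's actual headers.

    Matching is case-sensitive first; a case-insensitive fallback is accepted
    with a warning.
    """
    mapping: dict[str, str] = {}
    lower = {c.lower(): c for c in df.columns}
    for col in RATIO_COLUMNS:
        if col in df.columns:
            mapping[col] = col
        elif col.lower() in lower:
            mapping[col] = lower[col.lower()]
            logger.warning(
                "column %r matched case-insensitively as %r", col, mapping[col]
            )
        else:
            raise FormatError(f"bam_ratio file is missing required column {col!r}")
    return mapping


def _infer_window_size(windows: dict[str, list[CopyNumberWindow]]) -> int:
    diffs: Counter[int] = Counter()
    for ws in windows.values():
        for a, b in zip(ws, ws[1:]):
            diffs[b.start - a.start] += 1
    if not diffs:
        return 0
    return diffs.most_common(1)[0][0]


def read_bam_ratio(
    path: str | Path, valid_chromosomes: set[str], ploidy: int = 2
) -> GenomeCopyNumber:
    """Load a Control-FREEC bam_ratio file into a :class:`GenomeCopyNumber`.

    Rows on chromosomes outside ``valid_chromosomes`` (after ``chr``-prefix
    normalization) are discarded.  ``Start`` is converted from 1-based to
    0-based.  Linear ratios are stored as log2 values; sentinel rows
    (Ratio == -1) become state ``missing`` with NaN ratios.
    """
    path = Path(path)
    valid = {normalize_chrom(c) for c in valid_chromosomes}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row")
    cols = _resolve_columns(df)

    windows: dict[str, list[CopyNumberWindow]] = {}
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        chrom = normalize_chrom(str(rec[cols["Chromosome"]]))
        if chrom not in valid:
            n_dropped += 1
            continue
        try:
            start1 = int(rec[cols["Start"]])
            ratio = float(rec[cols["Ratio"]])
            median = float(rec[cols["MedianRatio"]])
            cn_raw = float(rec[cols["CopyNumber"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: non-numeric field ({exc})")
        if start1 < 1:
            raise FormatError(f"{path}: line {i}: Start must be >= 1, got {start1}")
        cn = int(cn_raw)
        if cn != cn_raw:
            logger.warning(
                "%s: line %d: fractional CopyNumber %s floored to %d",
                path, i, cn_raw, cn,
            )
        if ratio == MISSING_SENTINEL:
            w = CopyNumberWindow(
                chromosome=chrom,
                start=start1 - 1,
                log2_ratio=float("nan"),
                segment_median_log2=float("nan"),
                copy_number=cn,
                state=CNState.MISSING,
            )
        else:
            w = CopyNumberWindow(
                chromosome=chrom,
                start=start1 - 1,
                log2_ratio=math.log2(ratio) if ratio > 0 else float("-inf"),
                segment_median_log2=(
                    math.log2(median) if median > 0 else float("-inf")
                ),
                copy_number=cn,
                state=classify_state(cn, ploidy),
            )
        windows.setdefault(chrom, []).append(w)

    for ws in windows.values():
        ws.sort(key=lambda w: w.start)
    if n_dropped:
        logger.info(
            "%s: discarded %d rows on chromosomes outside the annotation",
            path, n_dropped,
        )
    genome = GenomeCopyNumber(
        windows=windows,
        ploidy=ploidy,
        window_size=_infer_window_size(windows),
        source_path=str(path),
    )
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzipped text, detecting gzip by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"|(\w+)\s+([^;\s]+)')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for m in _ATTR_RE.finditer(attr_field):
        if m.group(1):
            attrs.setdefault(m.group(1), m.group(2))
        else:
            attrs.setdefault(m.group(3), m.group(4))
    return attrs


def read_gtf(path: str | Path) -> GeneCatalog:
    """Parse a GTF file (plain or gzipped) into a :class:`GeneCatalog`.

    Genes come from ``gene`` features when present; a gene seen only through
    its ``exon`` features gets the span of those exons.  Coordinates are
    converted from 1-based inclusive to 0-based half-open.  Rows whose
    attribute field yields no gene identifier are skipped with a warning.
    """
    path = Path(path)
    gene_spans: dict[tuple[str, str], tuple[int, int]] = {}
    exon_lists: dict[tuple[str, str], list[tuple[int, int]]] = {}
    n_skipped = 0

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                logger.warning("%s: line %d: fewer than 9 fields, skipped", path, lineno)
                n_skipped += 1
                continue
            chrom_raw, _source, feature, start_s, end_s = fields[0], fields[1], fields[2], fields[3], fields[4]
            if feature not in ("gene", "exon"):
                continue
            attrs = _parse_attributes(fields[8])
            name = attrs.get("gene_name") or attrs.get("gene_id")
            if not name:
                logger.warning(
                    "%s: line %d: no gene_name/gene_id attribute, skipped",
                    path, lineno,
                )
                n_skipped += 1
                continue
            try:
                start = int(start_s) - 1  # 1-based inclusive -> 0-based half-open
                end = int(end_s)
            except ValueError:
                logger.warning("%s: line %d: non-numeric coordinates, skipped", path, lineno)
                n_skipped += 1
                continue
            chrom = normalize_chrom(chrom_raw)
            key = (chrom, name)
            if feature == "gene":
                gene_spans[key] = (start, end)
            else:
                exon_lists.setdefault(key, []).append((start, end))

    genes: list[Gene] = []
    for key in sorted(set(gene_spans) | set(exon_lists)):
        chrom, name = key
        exons = sorted(exon_lists.get(key, []))
        if key in gene_spans:
            start, end = gene_spans[key]
        else:
            start = min(s for s, _ in exons)
            end = max(e for _, e in exons)
        genes.append(Gene(name=name, chromosome=chrom, start=start, end=end, exons=exons))

    if not genes:
        raise FormatError(f"{path}: no genes could be parsed")
    if n_skipped:
        logger.info("%s: skipped %d unparseable lines", path, n_skipped)
    return GeneCatalog.from_genes(genes)


# ---------------------------------------------------------------------------
# cytoBand
# ---------------------------------------------------------------------------

def read_cytoband(path: str | Path, valid_chromosomes: set[str]) -> CytoBandSet:
    """Parse a UCSC 5-column cytoBand file (plain or gzipped).

    Each line: chromosome, start, end, band name, Giemsa stain.  Chromosomes
    outside ``valid_chromosomes`` are dropped; a stain outside the eight-value
    vocabulary is a format error.  Chromosome sizes are initialized from the
    last band end per chromosome (callers merge in gene extents via
    :func:`cnviz.model.chromosome_sizes`).
    """
    path = Path(path)
    valid = {normalize_chrom(c) for c in valid_chromosomes}
    segments: dict[str, list[CytoBandSegment]] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"{path}: line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom_raw, start_s, end_s, band_name, stain_s = fields
            try:
                stain = GiemsaStain(stain_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: unknown Giemsa stain {stain_s!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                )
            chrom = normalize_chrom(chrom_raw)
            if chrom not in valid:
                continue
            segments.setdefault(chrom, []).append(
                CytoBandSegment(
                    chromosome=chrom, start=start, end=end,
                    band_name=band_name, stain=stain,
                )
            )

    for segs in segments.values():
        segs.sort(key=lambda s: s.start)
    sizes = [
        (chrom, max(s.end for s in segs))
        for chrom, segs in segments.items()
    ]
    sizes.sort(key=lambda t: chrom_sort_key(t[0]))
    cyto = CytoBandSet(segments=segments, chromosome_sizes=sizes)
    cyto.validate()
    return cyto


def write_cytoband(cytobands: CytoBandSet, path: str | Path) -> None:
    """Write bands back out in the UCSC 5-column format."""
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom in sorted(cytobands.segments, key=chrom_sort_key):
            for seg in cytobands.segments[chrom]:
                fh.write(
                    f"{display_chrom(chrom)}\t{seg.start}\t{seg.end}\t"
                    f"{seg.band_name}\t{seg.stain.value}\n"
                )


# ---------------------------------------------------------------------------
# style persistence
# ---------------------------------------------------------------------------

def save_style(style: StyleConfig, path: str | Path) -> None:
    """Persist a style as a flat YAML key/value document."""
    style.validate()
    doc = asdict(style)
    doc["gain_color"] = list(style.gain_color)
    doc["loss_color"] = list(style.loss_color)
    doc["neutral_color"] = list(style.neutral_color)
    doc["ratio_chart_background"] = list(style.ratio_chart_background)
    doc["whole_exome_chart_background"] = list(style.whole_exome_chart_background)
    doc["aggregate_line_color"] = list(style.aggregate_line_color)
    doc["chromosome_palette"] = [list(c) for c in style.chromosome_palette]
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_style(path: str | Path) -> StyleConfig:
    """Load a style document; unknown keys warn and are ignored,
    invalid values raise."""
    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: style file must be a key/value document")
    known = set(StyleConfig.__dataclass_fields__)
    kwargs = {}
    for key, value in doc.items():
        if key not in known:
            logger.warning("%s: unknown style key %r ignored", path, key)
            continue
        if key.endswith("_color") or key.endswith("_background"):
            value = tuple(value)
        elif key == "chromosome_palette":
            value = [tuple(c) for c in value]
        kwargs[key] = value
    style = StyleConfig(**kwargs)
    try:
        style.validate()
    except ValueError as exc:
        raise FormatError(f"{path}: invalid style value: {exc}")
    return style
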
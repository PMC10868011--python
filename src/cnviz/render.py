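"""Figure rendering: whole-genome and single-chromosome copy-number views.

All figures are built headlessly on an Agg canvas (no display required).
Every render returns a :class:`LayoutMap` alongside the Figure so that the
geometry of a plot — chromosome offsets, marker counts per state, highlight
positions — can be asserted programmatically.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Polygon, Rectangle

from .core import genome_offsets, genes_in_region, windows_in_region
from .model import (
    CnvizError,
    CNState,
    CytoBandSet,
    Gene,
    GeneCatalog,
    GenomeCopyNumber,
    GiemsaStain,
    StyleConfig,
    ViewRegion,
    WHOLE_GENOME,
    display_chrom,
    normalize_chrom,
)

__all__ = [
    "LayoutMap",
    "render_whole_genome",
    "render_chromosome",
    "highlight_gene",
    "export_figure",
    "load_preset",
    "list_presets",
    "Y_RANGE",
    "CN_ZERO_FLOOR",
]

#: Default y-axis range for the log2-ratio panel; values outside are clamped.
Y_RANGE = (-5.0, 3.0)

#: Finite floor at which copy-number-zero (log2 = -inf) windows are drawn.
CN_ZERO_FLOOR = -5.0

#: Fixed salt so SVG element ids are reproducible across runs.
_SVG_HASHSALT = "cnviz"


def _rgb(color: tuple[int, int, int]) -> tuple[float, float, float]:
    return tuple(c / 255 for c in color)


@dataclass
class LayoutMap:
    """Assertable geometry of a rendered figure.

    ``marker_counts`` sums to the number of non-missing windows plotted;
    ``chromosome_offsets`` match :func:`cnviz.core.genome_offsets` for the
    plotted chromosome set; ``highlights`` records gene-highlight x positions
    in data coordinates.
    """

    chromosome_offsets: dict[str, int] = field(default_factory=dict)
    chromosome_extents: dict[str, tuple[int, int]] = field(default_factory=dict)
    track_extents: dict[str, tuple[float, float]] = field(default_factory=dict)
    marker_counts: dict[str, int] = field(
        default_factory=lambda: {"gain": 0, "loss": 0, "neutral": 0}
    )
    ideogram_segments: int = 0
    n_clamped: int = 0
    region: Optional[ViewRegion] = None
    highlights: list[dict] = field(default_factory=list)

    def total_markers(self) -> int:
        return sum(self.marker_counts.values())


def _clamp_y(y: float) -> tuple[float, bool]:
    if y == float("-inf") or y < Y_RANGE[0]:
        return Y_RANGE[0], True
    if y > Y_RANGE[1]:
        return Y_RANGE[1], True
    return y, False


def _new_figure(width: float, height: float, style: StyleConfig) -> Figure:
    fig = Figure(figsize=(width, height), dpi=100)
    FigureCanvasAgg(fig)
    fig.set_facecolor(_rgb(style.whole_exome_chart_background))
    return fig


def _scatter(ax, xs, ys, color, style: StyleConfig, clipped=None):
    """Draw markers; clipped points get a down-triangle clipping glyph."""
    clipped = clipped or [False] * len(xs)
    plain_x = [x for x, c in zip(xs, clipped) if not c]
    plain_y = [y for y, c in zip(ys, clipped) if not c]
    clip_x = [x for x, c in zip(xs, clipped) if c]
    clip_y = [y for y, c in zip(ys, clipped) if c]
    if plain_x:
        ax.scatter(
            plain_x, plain_y,
            s=style.marker_size**2, c=[color],
            alpha=style.marker_alpha, linewidths=0, marker="o",
        )
    if clip_x:
        ax.scatter(
            clip_x, clip_y,
            s=(style.marker_size * 1.5) ** 2, c=[color],
            alpha=style.marker_alpha, linewidths=0, marker="v",
        )


def render_whole_genome(
    genome: GenomeCopyNumber,
    cytobands: CytoBandSet,
    style: StyleConfig | None = None,
) -> tuple[Figure, LayoutMap]:
    """Scatter of log2 ratios along the concatenated genome.

    Each chromosome takes the next color of the chromosome palette (cycled);
    chromosome boundaries are separated by thin vertical lines and labelled
    at their centers.  The gene track is omitted in this view.
    """
    style = style or StyleConfig()
    style.validate()
    if not genome.windows:
        raise CnvizError("cannot render an empty genome")

    sizes = [
        (name, size)
        for name, size in cytobands.chromosome_sizes
        if name in genome.windows
    ]
    if not sizes:
        raise CnvizError("no chromosome in the copy-number data has a registered size")
    offsets = genome_offsets(sizes)
    total = sum(s for _, s in sizes)

    fig = _new_figure(14, 4, style)
    ax = fig.add_subplot(111)
    ax.set_facecolor(_rgb(style.ratio_chart_background))

    layout = LayoutMap(chromosome_offsets=dict(offsets))
    ws = genome.window_size or 1

    for i, (chrom, size) in enumerate(sizes):
        color = _rgb(style.chromosome_palette[i % len(style.chromosome_palette)])
        off = offsets[chrom]
        layout.chromosome_extents[chrom] = (off, off + size)
        xs, ys, clipped = [], [], []
        for w in genome.windows[chrom]:
            if w.state is CNState.MISSING:
                continue
            y, was_clamped = _clamp_y(w.log2_ratio)
            xs.append(off + w.start + ws / 2)
            ys.append(y)
            clipped.append(was_clamped)
            layout.marker_counts[w.state.value] += 1
            layout.n_clamped += was_clamped
        _scatter(ax, xs, ys, color, style, clipped)
        if i > 0:
            ax.axvline(off, color="0.7", linewidth=0.5, zorder=0)

    ax.set_xlim(0, total)
    ax.set_ylim(*Y_RANGE)
    ax.axhline(0.0, color="0.5", linewidth=0.6, zorder=0)
    ax.set_xticks([offsets[c] + s / 2 for c, s in sizes])
    ax.set_xticklabels(
        [display_chrom(c) for c, _ in sizes], rotation=90, fontsize=7
    )
    ax.set_ylabel("log2 copy-number ratio")
    layout.track_extents["ratio"] = Y_RANGE
    layout.region = ViewRegion(WHOLE_GENOME, 0, total)
    fig.tight_layout()
    return fig, layout


def _segment_runs(windows, ws: int):
    """Runs of consecutive windows sharing a segment median (the aggregation
    line is one step per run)."""
    runs = []
    for w in windows:
        y = w.segment_median_log2
        if math.isnan(y):
            continue
        y, _ = _clamp_y(y)
        if runs and runs[-1][2] == y and w.start <= runs[-1][1]:
            runs[-1][1] = w.start + ws
        else:
            runs.append([w.start, w.start + ws, y])
    return runs


def _draw_ideogram(ax, cytobands: CytoBandSet, chrom: str, region: ViewRegion,
                   layout: LayoutMap) -> None:
    size = cytobands.size_of(chrom)
    segs = cytobands.segments.get(chrom, [])
    for seg in segs:
        color = _rgb(cytobands.stain_colors[seg.stain])
        if seg.stain is GiemsaStain.ACEN:
            # centromeric band: triangle pointing toward the centromere side
            mid = (seg.start + seg.end) / 2
            if seg.start < size / 2:
                pts = [(seg.start, 0.1), (seg.start, 0.9), (seg.end, 0.5)]
            else:
                pts = [(seg.end, 0.1), (seg.end, 0.9), (seg.start, 0.5)]
            ax.add_patch(Polygon(pts, closed=True, facecolor=color,
                                 edgecolor="black", linewidth=0.4))
        else:
            ax.add_patch(Rectangle(
                (seg.start, 0.1), seg.end - seg.start, 0.8,
                facecolor=color, edgecolor="black", linewidth=0.4,
            ))
        layout.ideogram_segments += 1
    # displayed region marked in red on the ideogram
    ax.add_patch(Rectangle(
        (region.start, 0.0), region.span, 1.0,
        facecolor="none", edgecolor="red", linewidth=1.2,
    ))
    ax.set_xlim(0, size)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    ax.set_xlabel(f"{display_chrom(chrom)} position (bp)", fontsize=8)


def _draw_gene_track(ax, genes: list[Gene], region: ViewRegion) -> None:
    for g in genes:
        ax.hlines(0.5, g.start, g.end, color="black", linewidth=3)
        for es, ee in g.exons:
            ax.add_patch(Rectangle(
                (es, 0.3), max(ee - es, region.span * 0.001), 0.4,
                facecolor="black", edgecolor="none",
            ))
    if len(genes) <= 25:
        for g in genes:
            x = min(max(g.midpoint, region.start), region.end)
            ax.text(x, 0.05, g.name, ha="center", va="bottom",
                    fontsize=6, rotation=0)
    ax.set_xlim(region.start, region.end)
    ax.set_ylim(0, 1)
    ax.set_yticks([])
    ax.set_xticks([])


def render_chromosome(
    genome: GenomeCopyNumber,
    catalog: GeneCatalog,
    cytobands: CytoBandSet,
    chromosome: str,
    region: ViewRegion | None = None,
    style: StyleConfig | None = None,
) -> tuple[Figure, LayoutMap]:
    """Single-chromosome view: ratio scatter colored by gain/loss/neutral
    state, a step line over segment medians, a gene track, and an ideogram
    strip with the displayed region marked on it."""
    style = style or StyleConfig()
    style.validate()
    chrom = normalize_chrom(chromosome)
    if chrom not in genome.windows:
        raise CnvizError(
            f"unknown chromosome {chromosome!r}; available: "
            + ", ".join(genome.chromosomes())
        )
    size = cytobands.size_of(chrom)
    if region is None:
        region = ViewRegion(chrom, 0, size)
    elif normalize_chrom(region.chromosome) != chrom:
        raise CnvizError("region chromosome does not match the requested chromosome")

    fig = _new_figure(12, 6, style)
    gs = fig.add_gridspec(
        3, 1, height_ratios=[6, 1.2, 0.8], hspace=0.15,
    )
    ax_ratio = fig.add_subplot(gs[0])
    ax_genes = fig.add_subplot(gs[1], sharex=ax_ratio)
    ax_ideo = fig.add_subplot(gs[2])
    ax_ratio.set_facecolor(_rgb(style.ratio_chart_background))
    ax_genes.set_facecolor(_rgb(style.ratio_chart_background))

    layout = LayoutMap(
        chromosome_offsets={chrom: 0},
        chromosome_extents={chrom: (0, size)},
        region=region,
    )
    ws = genome.window_size or 1
    windows = windows_in_region(genome, region)

    state_colors = {
        CNState.GAIN: _rgb(style.gain_color),
        CNState.LOSS: _rgb(style.loss_color),
        CNState.NEUTRAL: _rgb(style.neutral_color),
    }
    for state, color in state_colors.items():
        xs, ys, clipped = [], [], []
        for w in windows:
            if w.state is not state:
                continue
            y, was_clamped = _clamp_y(w.log2_ratio)
            xs.append(w.start + ws / 2)
            ys.append(y)
            clipped.append(was_clamped)
            layout.n_clamped += was_clamped
        layout.marker_counts[state.value] = len(xs)
        _scatter(ax_ratio, xs, ys, color, style, clipped)

    # aggregation line: one horizontal step per segment-median run
    for x0, x1, y in _segment_runs(windows, ws):
        ax_ratio.hlines(
            y, max(x0, region.start), min(x1, region.end),
            color=_rgb(style.aggregate_line_color),
            linewidth=style.aggregate_line_thickness,
            zorder=3,
        )

    ax_ratio.set_xlim(region.start, region.end)
    ax_ratio.set_ylim(*Y_RANGE)
    ax_ratio.axhline(0.0, color="0.5", linewidth=0.6, zorder=0)
    ax_ratio.set_ylabel("log2 copy-number ratio")
    ax_ratio.set_title(display_chrom(chrom))

    genes = genes_in_region(catalog, region) if chrom in catalog.genes else []
    _draw_gene_track(ax_genes, genes, region)
    _draw_ideogram(ax_ideo, cytobands, chrom, region, layout)

    layout.track_extents["ratio"] = Y_RANGE
    layout.track_extents["genes"] = (0.0, 1.0)
    layout.track_extents["ideogram"] = (0.0, 1.0)
    return fig, layout


def highlight_gene(
    figure: Figure, layout: LayoutMap, gene: Gene
) -> tuple[Figure, LayoutMap]:
    """Draw a vertical highlight line at the gene's midpoint.

    In a whole-genome layout the x position is the chromosome offset plus the
    gene midpoint; in a chromosome layout it is the midpoint itself.  The
    highlight is recorded in ``layout.highlights``.
    """
    chrom = normalize_chrom(gene.chromosome)
    if chrom not in layout.chromosome_offsets:
        raise CnvizError(
            f"gene {gene.name!r} on chromosome {chrom!r} lies outside the "
            "rendered extent"
        )
    x = layout.chromosome_offsets[chrom] + gene.midpoint
    lo, hi = layout.chromosome_extents[chrom]
    if not (lo <= x <= hi):
        raise CnvizError(f"gene {gene.name!r} lies outside the rendered extent")
    ax = figure.axes[0]
    ax.axvline(x, color=(0.1, 0.3, 0.9), linewidth=1.2, zorder=4)
    ax.annotate(
        gene.name, xy=(x, Y_RANGE[1]), xytext=(0, -2),
        textcoords="offset points", ha="center", va="top",
        fontsize=7, color=(0.1, 0.3, 0.9),
    )
    layout.highlights.append({"name": gene.name, "x": x})
    return figure, layout


_RASTER_EXT = {".png"}
_VECTOR_EXT = {".svg", ".pdf"}


def export_figure(figure: Figure, path: str | Path, dpi: int = 300) -> None:
    """Write a figure to PNG (raster) or SVG/PDF (vector).

    The write is atomic (temp file + rename) so an error never leaves a
    partial output file.  SVG output is deterministic: element ids use a
    fixed hash salt and the creation date is stripped.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in _RASTER_EXT | _VECTOR_EXT:
        raise CnvizError(
            f"unsupported output format {ext!r}; supported: "
            + ", ".join(sorted(_RASTER_EXT | _VECTOR_EXT))
        )
    save_kwargs: dict = {"dpi": dpi}
    if ext == ".svg":
        save_kwargs["metadata"] = {"Date": None}
    elif ext == ".pdf":
        save_kwargs["metadata"] = {"CreationDate": None}

    fd, tmp = tempfile.mkstemp(suffix=ext, dir=path.parent or Path("."))
    os.close(fd)
    try:
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            figure.savefig(tmp, **save_kwargs)
        os.replace(tmp, path)
    except Exception:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# visual presets
# ---------------------------------------------------------------------------

def _preset_presentation_dark() -> StyleConfig:
    return StyleConfig(
        marker_size=4.0,
        marker_alpha=0.9,
        gain_color=(255, 80, 80),
        loss_color=(80, 220, 120),
        neutral_color=(170, 170, 170),
        ratio_chart_background=(25, 25, 30),
        whole_exome_chart_background=(15, 15, 18),
        aggregate_line_color=(255, 255, 255),
        aggregate_line_thickness=1.8,
        preset_name="presentation-dark",
    )


def _preset_publication_light() -> StyleConfig:
    return StyleConfig(
        marker_size=3.0,
        marker_alpha=0.7,
        gain_color=(214, 39, 40),
        loss_color=(44, 160, 44),
        neutral_color=(120, 120, 120),
        ratio_chart_background=(255, 255, 255),
        whole_exome_chart_background=(255, 255, 255),
        aggregate_line_color=(0, 0, 0),
        aggregate_line_thickness=1.5,
        preset_name="publication-light",
    )


def _preset_publication_warm() -> StyleConfig:
    # warm palette: gain in red, neutral in orange on a light background
    return StyleConfig(
        marker_size=3.0,
        marker_alpha=0.75,
        gain_color=(200, 30, 30),
        loss_color=(34, 139, 34),
        neutral_color=(255, 140, 0),
        ratio_chart_background=(255, 250, 240),
        whole_exome_chart_background=(253, 245, 230),
        aggregate_line_color=(80, 40, 20),
        aggregate_line_thickness=1.5,
        preset_name="publication-warm",
    )


_PRESETS = {
    "presentation-dark": _preset_presentation_dark,
    "publication-light": _preset_publication_light,
    "publication-warm": _preset_publication_warm,
}


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def load_preset(name: str) -> StyleConfig:
    """A complete StyleConfig for a named visual preset.

    Publication presets use light backgrounds; presentation presets dark.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise CnvizError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}"
        )
    style = factory()
    style.validate()
    return style
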
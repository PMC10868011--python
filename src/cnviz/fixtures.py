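"""Synthetic test-data generation: coherent toy bam_ratio + GTF + cytoBand
triples for genomes of arbitrary chromosome count, plus a canned
chronic-myeloid-leukemia blast-crisis scenario (Philadelphia-chromosome gains
on chr9/chr22; whole-chr7 loss with mixed loss/gain on chr17 including TP53).

The generator emulates the tabular surface of a read-depth CNA caller, not
the reads themselves: windows tile each chromosome, the linear ratio is
(CN / 2) perturbed by multiplicative log-normal noise (which keeps ratios
positive, as read-depth variability does), and the segment median is exact.
No GC bias, no subclonal fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import CnvizError, display_chrom, normalize_chrom

__all__ = [
    "ToyReference",
    "make_reference",
    "make_ratio_file",
    "cml_scenario",
    "CML_CASES",
]

#: stains cycled when tiling each toy chromosome with bands
_STAIN_CYCLE = (
    "gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk",
)

#: minimum room a gene needs inside its placement slot
_MIN_SLOT = 100


@dataclass
class ToyReference:
    """Paths and layout of one generated GTF/cytoBand pair."""

    gtf_path: Path
    cytoband_path: Path
    chromosome_sizes: list[tuple[str, int]] = field(default_factory=list)

    def __iter__(self):
        return iter((self.gtf_path, self.cytoband_path))

    def size_of(self, chromosome: str) -> int:
        chromosome = normalize_chrom(chromosome)
        for name, size in self.chromosome_sizes:
            if name == chromosome:
                return size
        raise KeyError(chromosome)


def _gene_name(chrom_idx: int, gene_idx: int, genes_per_chromosome: int) -> str:
    # fixed landmark genes: AUP1 mid-chr2, TP53 at the start of chr17's p arm
    if chrom_idx == 2 and gene_idx == genes_per_chromosome // 2:
        return "AUP1"
    if chrom_idx == 17 and gene_idx == 0:
        return "TP53"
    return f"G{chrom_idx}X{gene_idx}"


def make_reference(
    n_chromosomes: int,
    chromosome_size: int = 1_000_000,
    genes_per_chromosome: int = 10,
    bands_per_chromosome: int = 8,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> ToyReference:
    """Write a toy GTF and cytoBand pair for ``n_chromosomes`` chromosomes.

    Genes are non-overlapping (one per equal-width slot) with 1-5 exons each;
    bands tile each chromosome contiguously from 0 to ``chromosome_size``
    with stains cycling through all eight Giemsa classes.  A gene named AUP1
    is planted on chromosome 2 and, when the genome has at least 17
    chromosomes, one named TP53 at the start of chromosome 17 (inside its
    p arm).  Output is deterministic under ``seed``.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1 or bands_per_chromosome < 1:
        raise CnvizError("all fixture counts must be positive")
    chromosome_size = int(chromosome_size)
    slot = chromosome_size // genes_per_chromosome
    if slot < _MIN_SLOT:
        raise CnvizError(
            f"{genes_per_chromosome} genes do not fit a chromosome of "
            f"{chromosome_size} bp (slot {slot} < {_MIN_SLOT})"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gtf_lines: list[str] = []
    sizes: list[tuple[str, int]] = []
    for ci in range(1, n_chromosomes + 1):
        chrom = display_chrom(str(ci))
        sizes.append((str(ci), chromosome_size))
        for gi in range(genes_per_chromosome):
            lo = gi * slot
            margin = max(1, slot // 10)
            g_start = lo + margin + int(rng.integers(0, max(1, slot // 5)))
            g_len = int(slot * (0.2 + 0.4 * rng.random()))
            g_end = min(g_start + max(g_len, 50), lo + slot - margin)
            name = _gene_name(ci, gi, genes_per_chromosome)
            attrs = f'gene_id "{name}"; gene_name "{name}";'
            # GTF is 1-based inclusive
            gtf_lines.append(
                f"{chrom}\tcnviz\tgene\t{g_start + 1}\t{g_end}\t.\t+\t.\t{attrs}"
            )
            n_exons = int(rng.integers(1, 6))
            bounds = np.sort(
                rng.choice(np.arange(g_start, g_end), size=2 * n_exons, replace=False)
            ) if g_end - g_start >= 2 * n_exons else np.array([g_start, g_end - 1])
            for k in range(0, len(bounds) - 1, 2):
                es, ee = int(bounds[k]), int(bounds[k + 1]) + 1
                gtf_lines.append(
                    f"{chrom}\tcnviz\texon\t{es + 1}\t{ee}\t.\t+\t.\t{attrs}"
                )

    cyto_lines: list[str] = []
    band_edges = np.linspace(0, chromosome_size, bands_per_chromosome + 1).astype(int)
    for ci in range(1, n_chromosomes + 1):
        chrom = display_chrom(str(ci))
        for bi in range(bands_per_chromosome):
            stain = _STAIN_CYCLE[bi % len(_STAIN_CYCLE)]
            arm = "p" if band_edges[bi] < chromosome_size // 2 else "q"
            cyto_lines.append(
                f"{chrom}\t{band_edges[bi]}\t{band_edges[bi + 1]}\t"
                f"{arm}{bi + 1}\t{stain}"
            )

    gtf_path = out_dir / "reference.gtf"
    cytoband_path = out_dir / "cytoBand.txt"
    gtf_path.write_text("\n".join(gtf_lines) + "\n", encoding="utf-8")
    cytoband_path.write_text("\n".join(cyto_lines) + "\n", encoding="utf-8")
    return ToyReference(
        gtf_path=gtf_path, cytoband_path=cytoband_path, chromosome_sizes=sizes
    )


Event = tuple[str, int, int, int]  # chromosome, start, end, copy number


def _validate_events(reference: ToyReference, events: list[Event]) -> dict[str, list[Event]]:
    by_chrom: dict[str, list[Event]] = {}
    for chrom, start, end, cn in events:
        chrom = normalize_chrom(str(chrom))
        size = reference.size_of(chrom)
        if not (0 <= start < end <= size):
            raise CnvizError(
                f"event [{start}, {end}) outside chromosome {chrom} (size {size})"
            )
        if cn < 0:
            raise CnvizError(f"event copy number must be >= 0, got {cn}")
        by_chrom.setdefault(chrom, []).append((chrom, int(start), int(end), int(cn)))
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda e: e[1])
        for a, b in zip(evs, evs[1:]):
            if b[1] < a[2]:
                raise CnvizError(f"overlapping events on chromosome {chrom}")
    return by_chrom


def make_ratio_file(
    reference: ToyReference,
    events: list[Event] | None = None,
    window_size: int = 10_000,
    noise_sd: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
    out_path: str | Path = "ratio.txt",
) -> Path:
    """Write a bam_ratio file tiling the toy reference at ``window_size``.

    Baseline copy number is 2 everywhere; an event (chromosome, start, end,
    copy_number) overrides every window whose midpoint falls inside it
    (event coordinates effectively snap to window boundaries).  The emitted
    linear Ratio is (CN/2) * exp(N(0, noise_sd)); MedianRatio is the exact
    CN/2 of the window's segment; a ``missing_fraction`` of windows carry the
    -1 sentinel instead.  Deterministic under ``seed``.
    """
    by_chrom = _validate_events(reference, list(events or []))
    rng = np.random.default_rng(seed)
    out_path = Path(out_path)

    lines = ["Chromosome\tStart\tRatio\tMedianRatio\tCopyNumber"]
    for chrom, size in reference.chromosome_sizes:
        n_win = size // window_size
        starts = np.arange(n_win) * window_size
        cns = np.full(n_win, 2, dtype=int)
        for _, ev_start, ev_end, ev_cn in by_chrom.get(chrom, []):
            mids = starts + window_size / 2
            cns[(mids >= ev_start) & (mids < ev_end)] = ev_cn
        noise = (
            np.exp(rng.normal(0.0, noise_sd, size=n_win))
            if noise_sd > 0
            else np.ones(n_win)
        )
        missing = (
            rng.random(n_win) < missing_fraction
            if missing_fraction > 0
            else np.zeros(n_win, dtype=bool)
        )
        for i in range(n_win):
            start1 = int(starts[i]) + 1  # bam_ratio starts are 1-based
            median = cns[i] / 2
            if missing[i]:
                lines.append(f"{chrom}\t{start1}\t-1\t-1\t{cns[i]}")
            else:
                ratio = median * noise[i]
                lines.append(
                    f"{chrom}\t{start1}\t{ratio:.6g}\t{median:.6g}\t{cns[i]}"
                )
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path


CML_CASES = ("CML002BC", "CML004BC")


def cml_scenario(case: str, chromosome_size: int = 1_000_000) -> list[Event]:
    """Event list reproducing a known blast-crisis copy-number pattern on a
    toy genome of >= 22 equal chromosomes.

    ``CML002BC``: focal gains (CN=4) on chromosomes 9 and 22, the footprint
    of an amplified BCR::ABL1 fusion on the Philadelphia chromosome.
    ``CML004BC``: loss of the whole of chromosome 7 (CN=1) plus a
    heterogeneous chromosome 17 — p-arm loss (CN=1, covering the toy TP53
    gene at the chromosome start) and a focal gain (CN=3) on the q arm.
    """
    size = int(chromosome_size)
    if case == "CML002BC":
        return [
            ("9", int(0.40 * size), int(0.60 * size), 4),
            ("22", int(0.35 * size), int(0.65 * size), 4),
        ]
    if case == "CML004BC":
        return [
            ("7", 0, size, 1),
            ("17", 0, size // 2, 1),
            ("17", int(0.60 * size), int(0.85 * size), 3),
        ]
    raise CnvizError(
        f"unknown scenario {case!r}; available: {', '.join(CML_CASES)}"
    )
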
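# Methods

## Data model and conventions

`cnviz` holds three annotation layers in memory: per-chromosome ordered
lists of copy-number windows (`GenomeCopyNumber`), of genes with exon
intervals (`GeneCatalog`), and of cytogenetic bands (`CytoBandSet`).
All coordinates are 0-based half-open internally. GTF coordinates
(1-based inclusive) and bam_ratio `Start` values (1-based) are shifted at
parse time; UCSC cytoBand rows pass through unchanged. A single
convention removes off-by-one drift between tracks — the half-open overlap
test (`gene.start < region.end and gene.end > region.start`) is then the
same everywhere, and a gene that merely touches a region boundary does not
overlap it.

Chromosome names are matched after stripping a leading `chr` prefix,
because CNA-caller output and UCSC annotation routinely disagree on it;
the prefix is re-added for display. Ordering is natural: numeric
chromosomes ascending, then X, Y, M/MT, then anything else
lexicographically.

## Ratio semantics

The `Ratio` and `MedianRatio` columns are read as *linear* ratios on the
copy-number/ploidy scale (the convention of read-depth callers, where 1.0
means "at the baseline ploidy") and are log2-transformed at load. The
plotted value is therefore log2(CN/ploidy): 0 at baseline, −1 for a
single copy at ploidy 2, +1 for four copies. `--ploidy` generalizes the
denominator for non-diploid baselines. Gain/loss/neutral state comes from
the integer `CopyNumber` column compared with the ploidy (equality is
neutral — any other tie-break would color a normal diploid genome), never
from thresholding the continuous ratio.

Two degenerate inputs have defined behavior: a linear ratio of −1 is the
caller's sentinel for an unassessable window and becomes state `missing`
(kept in the container, excluded from every plot and statistic — the only
choice that keeps log2 defined); copy number 0 maps to −∞ and is drawn
clamped at the y-axis floor with a triangular clipping glyph.

## Chromosome sizes

The size of each chromosome is the maximum of its last cytoband end and
its last gene end. Band tables normally extend past the gene annotation,
but merging over both sources guarantees every plotted entity fits on its
axis regardless of which file reaches further; a chromosome with genes but
no bands is an error rather than a guess.

## Queries and zoom

Region queries run on the sorted per-chromosome lists with a bisect on
start positions followed by a filtered scan; the test suite checks them
against brute-force O(n) interval scans over randomized regions. Zoom-in
by factor f (2 or 10) divides the view span by f centered on an anchor
(default: the region midpoint); zoom-out multiplies it. Results clamp to
[0, chromosome size]; clamping at an edge shifts the window but preserves
the span, and a span larger than the chromosome yields the whole
chromosome. Away from edges, zoom-in then zoom-out by the same factor is
the identity.

## Rendering

Figures are built directly on an Agg canvas, so rendering works with no
display. The whole-genome view concatenates chromosomes on one x-axis
(cumulative offsets), cycles marker colors per chromosome from the
configurable palette, and omits the gene track. The single-chromosome
view stacks three panels: the log2-ratio scatter colored by state, a gene
track (thick black bars with exon ticks, labelled when ≤ 25 genes are
visible), and an ideogram strip with the displayed region boxed in red.
The aggregation line is a step function: consecutive windows sharing a
segment-median value form one horizontal run.

Giemsa stains map to fixed 24-bit colors — gneg white; gpos25/50/75/100 at
25/50/75/100 % gray; acen dark red, drawn as a triangle pointing toward
the centromere (standard ideogram idiom); gvar light gray; stalk pale
blue. The y-axis spans [−5, +3]; out-of-range values are clamped and
flagged with the clipping glyph. Every renderer returns a `LayoutMap`
recording offsets, per-state marker counts, ideogram segment counts and
highlight positions, which is what the tests assert against instead of
pixels.

SVG export is deterministic: element ids use a fixed hash salt and the
creation date is stripped, so identical inputs produce byte-identical
files. Writes are atomic (temp file + rename); a failed export never
leaves a partial file. Supported formats are PNG (raster, `--dpi`) and
SVG/PDF (vector).

Three visual presets are bundled: `publication-light` and
`publication-warm` on light backgrounds (warm uses red gains and orange
neutrals), `presentation-dark` on a dark background. A style file
(YAML key/value) persists marker size/alpha, all colors, backgrounds and
aggregate-line settings; unknown keys are ignored with a warning, invalid
values rejected.

## Reference registry

Identifiers hg38, hg19, mm39 and mm10 are always registered; they resolve
to *user-supplied* local GTF/cytoBand paths through a small YAML config
(`--refs-config`), and custom identifiers append after the built-ins.
Multi-hundred-megabyte annotation payloads do not belong in the package;
shipping identifiers plus locators keeps the interface while leaving
distribution to the user.

## Synthetic data generator

The generator fabricates coherent toy triples (GTF, cytoBand, bam_ratio)
so every code path is exercisable without downloads. It emulates the
*tabular surface* of a read-depth caller, not reads: windows tile each
chromosome at a fixed width (default 10 kb); the emitted linear ratio is
(CN/2)·exp(ε) with ε ~ N(0, noise_sd) — multiplicative log-normal noise
keeps ratios positive, as read-depth variability does; `MedianRatio` is
the exact CN/2 of the window's segment; a configurable fraction of windows
carries the −1 sentinel. Event regions (chromosome, start, end, CN)
override the diploid baseline for every window whose midpoint falls inside
them, so event edges snap to window boundaries. Genes are non-overlapping
(one per equal-width slot) with 1–5 exons; bands tile each chromosome
contiguously, cycling all eight stain classes. Landmark genes are planted
deterministically: *AUP1* mid-chromosome 2, and *TP53* at the start of
chromosome 17's p arm on genomes of ≥ 17 chromosomes.

Two canned event lists reproduce known chronic-myeloid-leukemia
blast-crisis patterns on a ≥ 22-chromosome toy genome: `CML002BC` — focal
CN=4 gains on chromosomes 9 and 22, the footprint of an amplified
BCR::ABL1 fusion on the Philadelphia chromosome; `CML004BC` — CN=1 loss of
all of chromosome 7, CN=1 loss of 17p (covering the toy *TP53*) and a
focal CN=3 gain on 17q.

What passing tests show, and what they do not: the generator has no GC
bias, no mappability structure, no subclonal mixtures and no
caller-specific segmentation artifacts, so green tests demonstrate correct
parsing, classification, geometry and rendering of well-formed caller
output — not robustness of any upstream CNA calling, which is out of
scope.

## Problem sizes

Default test and acceptance runs use 3-chromosome (and, for the
blast-crisis scenarios, 22-chromosome) genomes of 1 Mb per chromosome with
10 kb windows, 10 genes and 8 bands per chromosome — 100 windows per
chromosome. These sizes make every oracle (brute-force scans, raw-file
recounts) affordable while exercising the same code paths as
genome-scale input; nothing in the implementation depends on them.

## Known limitations

Interactive panning/tooltips and multi-sample overlays are out of scope.
GFF3 and BED are not read. The `Ratio` column must be linear; a
pre-logged input file would be shifted by a log2. Gene labels are
suppressed above 25 visible genes to avoid overplotting rather than
thinned intelligently.
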
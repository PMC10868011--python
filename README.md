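# cnviz

Headless, scriptable visualization and exploration of copy-number
alteration (CNA) data for cancer genomics. `cnviz` reads the tabular
per-window output of read-depth CNA callers such as Control-FREEC
(*bam_ratio* files), combines it with GTF gene annotation and UCSC
cytoBand ideogram tables, and renders publication-quality whole-genome and
single-chromosome figures — gain/loss/neutral markers, segment-median
aggregation lines, cytogenetic ideograms, gene tracks, zoom, and
gene-finding — entirely from the command line or from Python, with no
display attached.

## Who it is for

Researchers who have already called copy-number alterations (e.g. from
whole-exome or whole-genome sequencing of tumor samples) and want to
explore and publish the profiles without a GUI: batch figure generation on
a cluster, reproducible figures in a pipeline, or programmatic queries
("which windows overlap *TP53*, and are they lost?").

## The model

A *bam_ratio* file gives, per fixed-width genomic window, a linear
copy-number ratio and an integer copy-number call. `cnviz` plots each
window's value as a log2 ratio relative to the baseline ploidy *p*
(default 2):

    y = log2(CN / p)

so a diploid window sits at 0, a single-copy loss at −1, and a
four-copy gain at +1. Windows are classified **gain** (CN > *p*), **loss**
(CN < *p*) or **neutral** (CN = *p*) from the integer call, not by
thresholding the noisy ratio; windows the caller could not assess
(sentinel ratio −1) are kept as **missing** and excluded from plots and
statistics. A step line over the per-segment median log2 ratios summarizes
segmentation on top of the scatter. Chromosomes are drawn on a single
concatenated axis in natural order (1..22, X, Y, M), and windows on
chromosomes absent from the gene annotation are discarded at load.

Coordinates are 0-based half-open internally; GTF (1-based inclusive) and
bam_ratio starts (1-based) are converted at parse, and `chr` prefixes are
normalized away so UCSC and caller naming interoperate.

## Worked example

`cnviz` ships a synthetic-data generator, so the full workflow runs with no
downloads. Fabricate a 22-chromosome toy genome carrying a known
blast-crisis pattern — whole-chromosome-7 loss plus a heterogeneous
chromosome 17 (p-arm loss covering the toy *TP53*, focal q-arm gain) — and
render it:

```sh
$ cnviz make-fixtures --out-dir demo --n-chromosomes 22 --scenario CML004BC --seed 7
demo/reference.gtf
demo/cytoBand.txt
demo/ratio.txt

$ cnviz chromosome 17 --ratio demo/ratio.txt --gtf demo/reference.gtf \
        --cytoband demo/cytoBand.txt --out demo/chr17.png
INFO cnviz: loaded 2200 windows (2200 usable) on 22 chromosomes; 220 genes
INFO cnviz: wrote demo/chr17.png: region [0, 1000000), 100 markers

$ cnviz gene TP53 --ratio demo/ratio.txt --gtf demo/reference.gtf \
        --cytoband demo/cytoBand.txt --out demo/tp53.svg
INFO cnviz: loaded 2200 windows (2200 usable) on 22 chromosomes; 220 genes
INFO cnviz: wrote demo/tp53.svg: TP53 at 17:19804-49676 highlighted
```

The numbers mean: 22 chromosomes × 100 windows of 10 kb were parsed and
none were missing; the chromosome-17 view plots all 100 of its windows
(the p-arm half at y = −1 in the loss color, the focal gain at
y = log2(3/2) ≈ +0.58); the gene command located the toy *TP53* at
17:19,804–49,676, rendered a window around it and drew the vertical blue
highlight line at its midpoint. The PNG/SVG outputs carry the ratio panel,
a gene track (black bars with exon ticks), and a Giemsa-shaded ideogram
with the displayed region boxed in red.

Other entry points: `cnviz genome` (whole-genome view), `--zoom 2/10/-2/-10`
with `--from/--to` (region zoom), `--preset publication-warm|publication-light|presentation-dark`,
`--style saved.yaml` (persisted marker size/alpha, colors, backgrounds,
aggregate-line style), `cnviz refs` (registered reference pairs — hg38,
hg19, mm39, mm10 resolve to user-supplied local annotation paths via
`--refs-config`).

From Python, the same pieces are importable: `read_bam_ratio`, `read_gtf`,
`read_cytoband`, `find_gene`, `genes_in_region`, `windows_in_region`,
`apply_zoom`, `render_whole_genome`, `render_chromosome`,
`highlight_gene`, `export_figure`.

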
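"""Rendering: layout accounting, highlights, export formats, presets."""

import re
import xml.etree.ElementTree as ET

import pytest

from cnviz import fixtures, io
from cnviz.core import find_gene, windows_in_region
from cnviz.model import CnvizError, CNState, Gene, StyleConfig, ViewRegion
from cnviz.render import (
    export_figure,
    highlight_gene,
    list_presets,
    load_preset,
    render_chromosome,
    render_whole_genome,
)


class TestWholeGenomeView:
    def test_diploid_fixture_all_markers_neutral(self, diploid_genome,
                                                 toy_cytobands):
        fig, layout = render_whole_genome(diploid_genome, toy_cytobands)
        assert layout.marker_counts["gain"] == 0
        assert layout.marker_counts["loss"] == 0
        assert layout.marker_counts["neutral"] == diploid_genome.n_windows()

    def test_marker_total_equals_non_missing_window_count(
        self, tmp_path, toy_ref, toy_catalog, toy_cytobands
    ):
        p = fixtures.make_ratio_file(
            toy_ref, [], window_size=10_000, missing_fraction=0.2, seed=5,
            out_path=tmp_path / "m.txt",
        )
        g = io.read_bam_ratio(p, toy_catalog.valid_chromosomes)
        # oracle: sentinel rows counted straight off the emitted file
        with open(p) as fh:
            next(fh)
            rows = [line.split("\t") for line in fh]
        non_sentinel = sum(1 for r in rows if float(r[2]) != -1)
        assert non_sentinel < len(rows)
        _, layout = render_whole_genome(g, toy_cytobands)
        assert layout.total_markers() == non_sentinel == g.n_windows()

    def test_single_copy_chromosome_plots_at_minus_one(
        self, single_copy_chr3_genome, toy_cytobands
    ):
        fig, layout = render_whole_genome(single_copy_chr3_genome, toy_cytobands)
        ax = fig.axes[0]
        # chr3 occupies the last third of the concatenated axis
        off3 = layout.chromosome_offsets["3"]
        ys = {
            float(y)
            for coll in ax.collections
            for x, y in coll.get_offsets()
            if x >= off3
        }
        assert ys == {-1.0}

    def test_offsets_are_cumulative_and_chromosomes_colored_distinctly(
        self, diploid_genome, toy_cytobands
    ):
        fig, layout = render_whole_genome(diploid_genome, toy_cytobands)
        assert layout.chromosome_offsets == {"1": 0, "2": 1_000_000, "3": 2_000_000}
        ax = fig.axes[0]
        colors = {tuple(c.get_facecolor()[0]) for c in ax.collections if len(c.get_offsets())}
        assert len(colors) == 3

    def test_empty_genome_rejected(self, toy_cytobands):
        from cnviz.model import GenomeCopyNumber

        with pytest.raises(CnvizError, match="empty"):
            render_whole_genome(GenomeCopyNumber(), toy_cytobands)


@pytest.fixture(scope="module")
def gain_genome(tmp_path_factory, toy_ref, toy_catalog):
    p = fixtures.make_ratio_file(
        toy_ref, [("2", 300_000, 500_000, 3)], window_size=10_000,
        seed=4, out_path=tmp_path_factory.mktemp("gain") / "r.txt",
    )
    return io.read_bam_ratio(p, toy_catalog.valid_chromosomes)


class TestChromosomeView:
    def test_gain_marker_count_matches_event_windows(
        self, gain_genome, toy_catalog, toy_cytobands
    ):
        region = ViewRegion("2", 0, 1_000_000)
        _, layout = render_chromosome(
            gain_genome, toy_catalog, toy_cytobands, "2", region
        )
        expected_gain = sum(
            1 for w in gain_genome.windows["2"] if w.copy_number > 2
        )
        assert expected_gain == 20  # 200 kb event over 10 kb windows
        assert layout.marker_counts["gain"] == expected_gain
        assert layout.total_markers() == len(
            windows_in_region(gain_genome, region)
        )

    def test_all_diploid_chromosome_has_no_gain_or_loss(
        self, diploid_genome, toy_catalog, toy_cytobands
    ):
        _, layout = render_chromosome(
            diploid_genome, toy_catalog, toy_cytobands, "1"
        )
        assert layout.marker_counts["gain"] == 0
        assert layout.marker_counts["loss"] == 0

    def test_ideogram_segment_count_matches_cytoband_rows(
        self, diploid_genome, toy_catalog, toy_cytobands, toy_ref
    ):
        _, layout = render_chromosome(
            diploid_genome, toy_catalog, toy_cytobands, "chr1"
        )
        rows = sum(
            1 for line in open(toy_ref.cytoband_path)
            if line.startswith("chr1\t")
        )
        assert layout.ideogram_segments == rows == 8

    def test_unknown_chromosome_rejected(self, diploid_genome, toy_catalog,
                                         toy_cytobands):
        with pytest.raises(CnvizError, match="unknown chromosome"):
            render_chromosome(diploid_genome, toy_catalog, toy_cytobands, "99")


class TestHighlightGene:
    def test_highlight_lands_at_offset_plus_midpoint(
        self, diploid_genome, toy_catalog, toy_cytobands
    ):
        fig, layout = render_whole_genome(diploid_genome, toy_cytobands)
        (gene,) = find_gene(toy_catalog, "AUP1")
        highlight_gene(fig, layout, gene)
        expected = layout.chromosome_offsets["2"] + (gene.start + gene.end) / 2
        assert layout.highlights == [{"name": "AUP1", "x": expected}]

    def test_gene_at_chromosome_start(self, diploid_genome, toy_catalog,
                                      toy_cytobands):
        fig, layout = render_whole_genome(diploid_genome, toy_cytobands)
        g = Gene("EDGE", "1", 0, 1000)
        highlight_gene(fig, layout, g)
        assert layout.highlights[-1]["x"] == 500.0

    def test_two_calls_record_two_highlights(self, diploid_genome, toy_catalog,
                                             toy_cytobands):
        fig, layout = render_whole_genome(diploid_genome, toy_cytobands)
        for name in ("AUP1", "G1X0"):
            (gene,) = find_gene(toy_catalog, name)
            highlight_gene(fig, layout, gene)
        assert len(layout.highlights) == 2

    def test_gene_outside_rendered_extent_rejected(
        self, diploid_genome, toy_catalog, toy_cytobands
    ):
        fig, layout = render_chromosome(
            diploid_genome, toy_catalog, toy_cytobands, "1"
        )
        stray = Gene("X", "3", 0, 100)
        with pytest.raises(CnvizError, match="outside"):
            highlight_gene(fig, layout, stray)


class TestExport:
    @pytest.fixture()
    def figure(self, diploid_genome, toy_cytobands):
        fig, _ = render_whole_genome(diploid_genome, toy_cytobands)
        return fig

    def test_svg_is_well_formed_xml_with_markers(self, figure, tmp_path):
        out = tmp_path / "fig.svg"
        export_figure(figure, out)
        root = ET.parse(out).getroot()
        assert root.tag.endswith("svg")
        assert b"<use" in out.read_bytes() or b"<path" in out.read_bytes()

    def test_png_magic_bytes(self, figure, tmp_path):
        out = tmp_path / "fig.png"
        export_figure(figure, out, dpi=72)
        assert out.read_bytes()[:8] == b"\x89PNG\r\n\x1a\n"

    def test_pdf_written_nonempty(self, figure, tmp_path):
        out = tmp_path / "fig.pdf"
        export_figure(figure, out)
        assert out.read_bytes()[:5] == b"%PDF-"

    def test_unsupported_extension_lists_formats(self, figure, tmp_path):
        with pytest.raises(CnvizError, match=r"\.png.*\.svg|\.svg.*\.png"):
            export_figure(figure, tmp_path / "fig.bmp")

    def test_svg_output_is_deterministic(self, diploid_genome, toy_cytobands,
                                         tmp_path):
        outs = []
        for i in range(2):
            fig, _ = render_whole_genome(diploid_genome, toy_cytobands)
            out = tmp_path / f"fig{i}.svg"
            export_figure(fig, out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_marker_size_change_alters_only_marker_geometry(
        self, diploid_genome, toy_cytobands, tmp_path
    ):
        texts = []
        for size in (3, 9):
            style = StyleConfig(marker_size=size)
            fig, _ = render_whole_genome(diploid_genome, toy_cytobands, style)
            out = tmp_path / f"s{size}.svg"
            export_figure(fig, out)
            texts.append(out.read_text())
        assert texts[0] != texts[1]

        def strip_marker_geometry(text):
            # marker radii live in <defs> path definitions and their hashed ids
            text = re.sub(r'<path id="[^"]*" d="[^"]*"/>', "", text)
            return re.sub(r'xlink:href="#[^"]*"', "", text)

        assert strip_marker_geometry(texts[0]) == strip_marker_geometry(texts[1])


class TestPresets:
    def test_registered_presets_are_valid_styles(self):
        names = list_presets()
        assert {"presentation-dark", "publication-light",
                "publication-warm"} <= set(names)
        for name in names:
            style = load_preset(name)
            style.validate()
            assert style.preset_name == name

    def test_publication_warm_is_red_gain_on_light_background(self):
        s = load_preset("publication-warm")
        r, g, b = s.gain_color
        assert r > 150 and r > g and r > b  # red family
        assert sum(s.ratio_chart_background) > 600  # light

    def test_presentation_preset_is_dark(self):
        s = load_preset("presentation-dark")
        assert sum(s.ratio_chart_background) < 300

    def test_unknown_preset_error_lists_available(self):
        with pytest.raises(CnvizError, match="publication-warm"):
            load_preset("neon")
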
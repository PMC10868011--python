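"""Shared fixtures: small synthetic genomes built once per session."""

from __future__ import annotations

import pytest

from cnviz import fixtures, io
from cnviz.model import chromosome_sizes, valid_chromosome_set


@pytest.fixture(scope="session")
def toy_ref(tmp_path_factory):
    """3 chromosomes of 1 Mb, 10 genes and 8 bands each."""
    out = tmp_path_factory.mktemp("toy_ref")
    return fixtures.make_reference(
        n_chromosomes=3,
        chromosome_size=1_000_000,
        genes_per_chromosome=10,
        bands_per_chromosome=8,
        seed=1,
        out_dir=out,
    )


@pytest.fixture(scope="session")
def toy_catalog(toy_ref):
    return io.read_gtf(toy_ref.gtf_path)


@pytest.fixture(scope="session")
def toy_cytobands(toy_ref, toy_catalog):
    cyto = io.read_cytoband(toy_ref.cytoband_path, valid_chromosome_set(toy_catalog))
    cyto.chromosome_sizes = chromosome_sizes(cyto, toy_catalog)
    return cyto


@pytest.fixture(scope="session")
def diploid_ratio_path(tmp_path_factory, toy_ref):
    """Noise-free diploid baseline over the toy reference."""
    out = tmp_path_factory.mktemp("ratio") / "diploid.txt"
    return fixtures.make_ratio_file(
        toy_ref, events=[], window_size=10_000, noise_sd=0.0,
        missing_fraction=0.0, seed=1, out_path=out,
    )


@pytest.fixture(scope="session")
def diploid_genome(diploid_ratio_path, toy_catalog):
    return io.read_bam_ratio(
        diploid_ratio_path, valid_chromosome_set(toy_catalog), ploidy=2
    )


@pytest.fixture(scope="session")
def single_copy_chr3_genome(tmp_path_factory, toy_ref, toy_catalog):
    """Noise-free genome with the whole of chr3 at a single copy."""
    out = tmp_path_factory.mktemp("ratio_cn1") / "cn1.txt"
    path = fixtures.make_ratio_file(
        toy_ref, events=[("3", 0, 1_000_000, 1)], window_size=10_000,
        noise_sd=0.0, missing_fraction=0.0, seed=1, out_path=out,
    )
    return io.read_bam_ratio(path, valid_chromosome_set(toy_catalog), ploidy=2)


@pytest.fixture(scope="session")
def cml_ref(tmp_path_factory):
    """22-chromosome toy genome used by the blast-crisis scenarios."""
    out = tmp_path_factory.mktemp("cml_ref")
    return fixtures.make_reference(
        n_chromosomes=22,
        chromosome_size=1_000_000,
        genes_per_chromosome=10,
        bands_per_chromosome=8,
        seed=2,
        out_dir=out,
    )


@pytest.fixture(scope="session")
def cml_catalog(cml_ref):
    return io.read_gtf(cml_ref.gtf_path)


@pytest.fixture(scope="session")
def cml_cytobands(cml_ref, cml_catalog):
    cyto = io.read_cytoband(cml_ref.cytoband_path, valid_chromosome_set(cml_catalog))
    cyto.chromosome_sizes = chromosome_sizes(cyto, cml_catalog)
    return cyto
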
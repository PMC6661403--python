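"""Shared fixtures: all test data is generated at test time."""

from __future__ import annotations

import pytest

from annoverlap.annotation_io import harmonize, parse_gff3, parse_gtf
from annoverlap.model import ENSEMBL, NCBI, AnnotationSet, GeneModel, GenomicInterval
from annoverlap.overlap import AorParams, run_overlap_pipeline
from annoverlap.simulate import (
    BlastConfig,
    ComparaConfig,
    GeneInfoConfig,
    ScenarioConfig,
    generate_annotation_pair,
    generate_blast_tab,
    generate_compara_tables,
    generate_gene_info,
)


def iv(chrom, start, end, strand="+"):
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)


def gene(gene_id, source, chrom, start, end, exons=(), cds=(), strand="+"):
    return GeneModel(
        gene_id=gene_id,
        source=source,
        span=iv(chrom, start, end, strand),
        exons=[iv(chrom, a, b, strand) for a, b in exons],
        cds=[iv(chrom, a, b, strand) for a, b in cds],
    )


def ncbi_set(*genes, assembly="Asm1"):
    return AnnotationSet(source=NCBI, assembly=assembly, genes=list(genes))


def ensembl_set(*genes, assembly="Asm1"):
    return AnnotationSet(source=ENSEMBL, assembly=assembly, genes=list(genes))


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """The standard planted scenario, written to disk once per session."""
    out = tmp_path_factory.mktemp("scenario")
    gff3, gtf, truth = generate_annotation_pair(ScenarioConfig(seed=17), str(out))
    return {"dir": str(out), "gff3": gff3, "gtf": gtf, "truth": truth}


@pytest.fixture(scope="session")
def scenario_sets(scenario):
    """Parsed + harmonized annotation sets of the standard scenario."""
    ncbi = parse_gff3(scenario["gff3"])
    ens = parse_gtf(scenario["gtf"])
    return harmonize(ncbi, ens)


@pytest.fixture(scope="session")
def aor_result(scenario_sets):
    ncbi, ens = scenario_sets
    return run_overlap_pipeline(ncbi, ens, AorParams())


@pytest.fixture(scope="session")
def gene_info_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("geneinfo") / "gene_info.tsv"
    truth = generate_gene_info(GeneInfoConfig(seed=17), str(out))
    return {"path": str(out), "truth": truth}


@pytest.fixture(scope="session")
def compara_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("compara")
    truth = generate_compara_tables(ComparaConfig(seed=17), str(out))
    return truth


@pytest.fixture(scope="session")
def blast_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("blast")
    truth = generate_blast_tab(BlastConfig(seed=17), str(out))
    return truth
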
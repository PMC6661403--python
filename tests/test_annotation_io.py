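"""Parsing, harmonization and serialization of GFF3/GTF annotation."""

import random

import pytest

from annoverlap.annotation_io import (
    harmonize,
    load_alias_map,
    parse_gff3,
    parse_gtf,
    write_gff3,
    write_gtf,
)
from annoverlap.model import (
    AnnotationParseError,
    AssemblyMismatchError,
)

GFF3_SMALL = """##gff-version 3
##genome-build Asm1
1\tRefSeq\tgene\t100\t200\t.\t+\t.\tID=gene-A;Dbxref=GeneID:111;Name=TP53;gene_biotype=protein_coding
1\tRefSeq\tmRNA\t100\t200\t.\t+\t.\tID=rna-A;Parent=gene-A
1\tRefSeq\texon\t100\t150\t.\t+\t.\tID=exon-1;Parent=rna-A
1\tRefSeq\texon\t160\t200\t.\t+\t.\tID=exon-2;Parent=rna-A
1\tRefSeq\tCDS\t110\t140\t.\t+\t0\tID=cds-1;Parent=rna-A
"""

GTF_EXONS_ONLY = """#!genome-build Asm1
1\tensembl\texon\t100\t150\t.\t+\t.\tgene_id "ENSTEST1"; transcript_id "ENST1";
1\tensembl\texon\t300\t400\t.\t+\t.\tgene_id "ENSTEST1"; transcript_id "ENST1";
"""

GTF_WITH_GENE = """#!genome-build Asm1
1\tensembl\tgene\t50\t500\t.\t+\t.\tgene_id "ENSG1"; gene_name "TP53";
1\tensembl\ttranscript\t100\t400\t.\t+\t.\tgene_id "ENSG1"; transcript_id "ENST1";
1\tensembl\texon\t100\t150\t.\t+\t.\tgene_id "ENSG1"; transcript_id "ENST1";
1\tensembl\texon\t300\t400\t.\t+\t.\tgene_id "ENSG1"; transcript_id "ENST1";
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestParseGff3:
    def test_small_fixture(self, tmp_path):
        aset = parse_gff3(_write(tmp_path, "a.gff3", GFF3_SMALL))
        assert len(aset) == 1
        g = aset.genes[0]
        assert g.gene_id == "111"
        assert g.symbol == "TP53"
        assert g.biotype == "protein_coding"
        assert [(e.start, e.end) for e in g.exons] == [(100, 150), (160, 200)]
        assert [(c.start, c.end) for c in g.cds] == [(110, 140)]
        assert aset.assembly == "Asm1"

    def test_header_only_file(self, tmp_path):
        aset = parse_gff3(_write(tmp_path, "e.gff3", "##gff-version 3\n"))
        assert len(aset) == 0

    def test_duplicate_geneid_on_scaffold_is_parsed_and_flagged(self, tmp_path):
        text = GFF3_SMALL + (
            "NW_0001.1\tRefSeq\tgene\t500\t700\t.\t+\t.\t"
            "ID=gene-A2;Dbxref=GeneID:111\n"
        )
        aset = parse_gff3(_write(tmp_path, "d.gff3", text))
        assert len(aset) == 2
        assert aset.duplicate_ids() == {"111"}

    def test_malformed_line_names_line_number(self, tmp_path):
        text = GFF3_SMALL + "1\tRefSeq\tgene\tnotanumber\t900\t.\t+\t.\tID=x\n"
        with pytest.raises(AnnotationParseError, match="line 8"):
            parse_gff3(_write(tmp_path, "bad.gff3", text))

    def test_gene_without_id_is_skipped_and_counted(self, tmp_path):
        text = "##gff-version 3\n1\tRefSeq\tgene\t10\t20\t.\t+\t.\tID=gene-noid\n"
        aset = parse_gff3(_write(tmp_path, "n.gff3", text))
        assert len(aset) == 0
        assert aset.skipped == [("gene-noid", "no_gene_id")]


class TestParseGtf:
    def test_gene_line_defines_span(self, tmp_path):
        aset = parse_gtf(_write(tmp_path, "g.gtf", GTF_WITH_GENE))
        assert len(aset) == 1
        g = aset.genes[0]
        assert (g.span.start, g.span.end) == (50, 500)
        assert g.symbol == "TP53"
        assert len(g.exons) == 2

    def test_exons_only_span_is_envelope(self, tmp_path):
        aset = parse_gtf(_write(tmp_path, "x.gtf", GTF_EXONS_ONLY))
        g = aset.genes[0]
        assert g.gene_id == "ENSTEST1"
        assert (g.span.start, g.span.end) == (100, 400)

    def test_identical_spans_distinct_ids_give_two_genes(self, tmp_path):
        text = GTF_WITH_GENE + GTF_WITH_GENE.replace("ENSG1", "ENSG2").replace("#!genome-build Asm1\n", "")
        aset = parse_gtf(_write(tmp_path, "two.gtf", text))
        assert sorted(g.gene_id for g in aset.genes) == ["ENSG1", "ENSG2"]
        spans = {(g.span.start, g.span.end) for g in aset.genes}
        assert spans == {(50, 500)}


class TestHarmonize:
    def test_alt_locus_duplicate_reduced_to_primary(self, tmp_path):
        text = GFF3_SMALL + (
            "NW_0001.1\tRefSeq\tgene\t500\t700\t.\t+\t.\t"
            "ID=gene-A2;Dbxref=GeneID:111\n"
        )
        ncbi = parse_gff3(_write(tmp_path, "d.gff3", text))
        ens = parse_gtf(_write(tmp_path, "g.gtf", GTF_WITH_GENE))
        ncbi, ens = harmonize(ncbi, ens)
        assert [g.chrom for g in ncbi.genes if g.gene_id == "111"] == ["1"]
        assert ("111", "duplicate_on:NW_0001.1") in ncbi.skipped

    def test_assembly_mismatch_is_hard_error(self, tmp_path):
        ncbi = parse_gff3(_write(tmp_path, "a.gff3", GFF3_SMALL), assembly="Sscrofa11.1")
        ens = parse_gtf(_write(tmp_path, "g.gtf", GTF_WITH_GENE), assembly="Sscrofa10.2")
        with pytest.raises(AssemblyMismatchError, match="Sscrofa1"):
            harmonize(ncbi, ens)

    def test_alias_map_renames_and_drop_sentinel_drops(self, tmp_path):
        text = GFF3_SMALL.replace("\n1\t", "\nchr1\t") + (
            "weird_scaffold\tRefSeq\tgene\t10\t20\t.\t+\t.\tID=g2;Dbxref=GeneID:222\n"
        )
        ncbi = parse_gff3(_write(tmp_path, "c.gff3", text))
        ens = parse_gtf(_write(tmp_path, "g.gtf", GTF_WITH_GENE))
        aliases = {"chr1": "1", "weird_scaffold": "."}
        ncbi, _ = harmonize(ncbi, ens, alias_map=aliases)
        assert [g.chrom for g in ncbi.genes] == ["1"]
        assert ("222", "unmappable_chromosome:weird_scaffold") in ncbi.skipped

    def test_default_alias_map_loads(self):
        aliases = load_alias_map()
        assert aliases["chr1"] == "1"
        assert aliases["chrM"] == "MT"

    def test_gene_ids_unique_after_harmonize(self, scenario_sets):
        for aset in scenario_sets:
            assert not aset.duplicate_ids()


class TestRoundTrip:
    def test_gff3_round_trip(self, scenario_sets, tmp_path):
        ncbi, _ = scenario_sets
        p = tmp_path / "rt.gff3"
        write_gff3(ncbi, str(p))
        again = parse_gff3(str(p))
        assert again.genes == ncbi.genes
        assert again.assembly == ncbi.assembly

    def test_gtf_round_trip(self, scenario_sets, tmp_path):
        _, ens = scenario_sets
        p = tmp_path / "rt.gtf"
        write_gtf(ens, str(p))
        again = parse_gtf(str(p))
        assert again.genes == ens.genes

    def test_parse_is_line_order_invariant(self, tmp_path):
        lines = GTF_WITH_GENE.strip().split("\n")
        header, body = lines[0], lines[1:]
        random.Random(7).shuffle(body)
        shuffled = "\n".join([header] + body) + "\n"
        a = parse_gtf(_write(tmp_path, "orig.gtf", GTF_WITH_GENE))
        b = parse_gtf(_write(tmp_path, "shuf.gtf", shuffled))
        assert a.genes == b.genes
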
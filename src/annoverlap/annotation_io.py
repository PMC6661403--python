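"""Reading, harmonizing and writing NCBI GFF3 and Ensembl GTF annotation.

Both providers annotate the same assemblies but disagree in dialect: NCBI
ships GFF3 whose gene features carry the Entrez ID in ``Dbxref=GeneID:``,
Ensembl ships GTF keyed by ``gene_id``. This module reduces both to the
common :class:`~annoverlap.model.GeneModel` (gene span + exon and CDS
interval lists) so that the position-based pairing in
:mod:`annoverlap.overlap` can compare them.

Parsing is delegated to :mod:`gffutils` (which also resolves the
gene → mRNA → exon parent chain and infers GTF gene spans as the envelope of
their exons); a validation pre-pass of our own reports malformed lines with
their line numbers.
"""

from __future__ import annotations

import csv
import os
import re
from typing import Optional

import gffutils

from .model import (
    ENSEMBL,
    NCBI,
    AnnotationParseError,
    AnnotationSet,
    AssemblyMismatchError,
    GeneModel,
    GenomicInterval,
)

#: Feature types treated as genes. Everything outside gene/transcript/exon/CDS
#: feature classes is ignored — only genes, exons and CDS enter the pairing.
GENE_TYPES = frozenset({"gene", "pseudogene"})
_GENOME_BUILD_RE = re.compile(r"^#+!?\s*genome-build\s+(?:\S+\s+)?(\S+)")

#: Alias-map value that drops a gene instead of renaming its chromosome.
DROP_CHROM = "."

_DEFAULT_ALIAS_PATH = os.path.join(os.path.dirname(__file__), "data", "chrom_aliases.tsv")


def _read_assembly_header(lines: list[str]) -> Optional[str]:
    for line in lines:
        if not line.startswith("#"):
            break
        m = _GENOME_BUILD_RE.match(line)
        if m:
            return m.group(1)
    return None


def _validate_lines(path: str) -> list[str]:
    """Check the 9-column tab layout; raise naming the first bad line."""
    lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            lines.append(line)
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{cols[3]!r}/{cols[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end}]"
                )
    return lines


def _first_attr(feature, *keys: str) -> Optional[str]:
    for key in keys:
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    return None


def _entrez_from_dbxref(feature) -> Optional[str]:
    for val in feature.attributes.get("Dbxref", []):
        if val.startswith("GeneID:"):
            return val.split(":", 1)[1]
    return None


def _collect_features(db, gene, featuretype: str, strand: str) -> list[GenomicInterval]:
    """Flatten all descendant features of one type into unique sorted intervals.

    Multiple transcripts repeat the same exon/CDS coordinates; duplicates are
    collapsed so the element-wise overlap means are not weighted by isoform
    count.
    """
    seen: set[tuple[int, int]] = set()
    out: list[GenomicInterval] = []
    for feat in db.children(gene, featuretype=featuretype):
        key = (feat.start, feat.end)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            GenomicInterval(chrom=gene.seqid, start=feat.start, end=feat.end, strand=strand)
        )
    out.sort(key=lambda iv: (iv.start, iv.end))
    return out


def _build_db(lines: list[str]):
    # only infer GTF gene/transcript envelopes when explicit lines are absent
    types_present = {line.split("\t")[2] for line in lines if line and not line.startswith("#")}
    data = "\n".join(lines) + "\n"
    return gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes="gene" in types_present,
        disable_infer_transcripts=bool({"transcript", "mRNA"} & types_present),
        verbose=False,
    )


def _parse(path: str, source: str, assembly: Optional[str]) -> AnnotationSet:
    lines = _validate_lines(path)
    header_assembly = _read_assembly_header(lines)
    aset = AnnotationSet(source=source, assembly=assembly or header_assembly)
    if not any(line and not line.startswith("#") for line in lines):
        return aset
    db = _build_db(lines)
    for gene in db.features_of_type(sorted(GENE_TYPES)):
        if source == NCBI:
            gene_id = _entrez_from_dbxref(gene) or _first_attr(gene, "gene_id")
        else:
            gene_id = _first_attr(gene, "gene_id")
        if not gene_id:
            aset.skipped.append((gene.id or f"{gene.seqid}:{gene.start}", "no_gene_id"))
            continue
        strand = gene.strand if gene.strand in ("+", "-") else "."
        span = GenomicInterval(chrom=gene.seqid, start=gene.start, end=gene.end, strand=strand)
        if source == NCBI:
            symbol = _first_attr(gene, "Name", "gene")
        else:
            symbol = _first_attr(gene, "gene_name")
        biotype = _first_attr(gene, "gene_biotype", "biotype")
        aset.genes.append(
            GeneModel(
                gene_id=gene_id,
                source=source,
                span=span,
                exons=_collect_features(db, gene, "exon", strand),
                cds=_collect_features(db, gene, "CDS", strand),
                symbol=symbol,
                biotype=biotype,
            )
        )
    aset.genes.sort(key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id))
    return aset


def parse_gff3(path: str, assembly: Optional[str] = None) -> AnnotationSet:
    """Parse an NCBI-style GFF3 file into an :class:`AnnotationSet`.

    Entrez IDs are taken from ``Dbxref=GeneID:`` first, then from a
    ``gene_id`` attribute. Gene features without a resolvable ID are skipped
    and recorded in ``AnnotationSet.skipped``. Genes on alternative-locus
    scaffolds are retained here; :func:`harmonize` resolves the duplicates.
    """
    return _parse(path, NCBI, assembly)


def parse_gtf(path: str, assembly: Optional[str] = None) -> AnnotationSet:
    """Parse an Ensembl-style GTF file into an :class:`AnnotationSet`.

    When a file carries no explicit gene feature lines the gene span is the
    envelope of its exons (via gffutils' gene inference).
    """
    return _parse(path, ENSEMBL, assembly)


def load_alias_map(path: Optional[str] = None) -> dict[str, str]:
    """Load a two-column chromosome alias map (``name<TAB>canonical``).

    A canonical value of ``.`` drops genes on that sequence. Without an
    explicit path the small default map shipped with the package (``chrN`` →
    ``N``, mitochondrial synonyms → ``MT``) is returned.
    """
    p = path or _DEFAULT_ALIAS_PATH
    aliases: dict[str, str] = {}
    with open(p) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise AnnotationParseError(f"{p}: line {lineno}: expected 2 columns")
            aliases[cols[0]] = cols[1]
    return aliases


def _apply_aliases(aset: AnnotationSet, aliases: dict[str, str]) -> AnnotationSet:
    genes: list[GeneModel] = []
    for g in aset.genes:
        target = aliases.get(g.chrom, g.chrom)
        if target == DROP_CHROM:
            aset.skipped.append((g.gene_id, f"unmappable_chromosome:{g.chrom}"))
            continue
        if target == g.chrom:
            genes.append(g)
            continue
        rename = lambda iv: GenomicInterval(target, iv.start, iv.end, iv.strand)  # noqa: E731
        genes.append(
            GeneModel(
                gene_id=g.gene_id,
                source=g.source,
                span=rename(g.span),
                exons=[rename(iv) for iv in g.exons],
                cds=[rename(iv) for iv in g.cds],
                symbol=g.symbol,
                biotype=g.biotype,
            )
        )
    aset.genes = genes
    return aset


def _dedup_alt_loci(aset: AnnotationSet) -> AnnotationSet:
    """Reduce genes whose ID occurs on several sequences to one copy.

    The copy on the primary assembly (sequence name not prefixed ``NT_`` /
    ``NW_``) wins; among several candidates the longest span, then the
    lexicographically smallest chromosome, keeps the choice deterministic.
    """
    by_id: dict[str, list[GeneModel]] = {}
    for g in aset.genes:
        by_id.setdefault(g.gene_id, []).append(g)
    genes: list[GeneModel] = []
    for gene_id, copies in by_id.items():
        if len(copies) == 1:
            genes.append(copies[0])
            continue
        copies.sort(key=lambda g: (g.on_alt_locus(), -g.span.width, g.chrom))
        keep = copies[0]
        genes.append(keep)
        for other in copies[1:]:
            aset.skipped.append((gene_id, f"duplicate_on:{other.chrom}"))
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.span.end, g.gene_id))
    aset.genes = genes
    return aset


def harmonize(
    ncbi: AnnotationSet,
    ensembl: AnnotationSet,
    alias_map: Optional[dict[str, str]] = None,
) -> tuple[AnnotationSet, AnnotationSet]:
    """Make the two annotation sets comparable.

    Checks that both sets describe the same assembly (a hard error
    otherwise — positions on different assemblies cannot be compared),
    reconciles chromosome naming through the alias map, and restores
    per-source gene-ID uniqueness by collapsing alternative-locus duplicates
    onto the primary-assembly copy.
    """
    if ncbi.assembly and ensembl.assembly and ncbi.assembly != ensembl.assembly:
        raise AssemblyMismatchError(
            f"assembly mismatch: NCBI={ncbi.assembly!r} vs Ensembl={ensembl.assembly!r}"
        )
    aliases = alias_map if alias_map is not None else load_alias_map()
    ncbi = _dedup_alt_loci(_apply_aliases(ncbi, aliases))
    ensembl = _dedup_alt_loci(_apply_aliases(ensembl, aliases))
    return ncbi, ensembl


def write_skip_report(aset: AnnotationSet, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene_id", "reason"])
        for gene_id, reason in aset.skipped:
            w.writerow([gene_id, reason])


def _gff3_attrs(g: GeneModel, uid: str, which: str, idx: int = 0) -> str:
    if which == "gene":
        parts = [f"ID=gene-{uid}", f"Dbxref=GeneID:{g.gene_id}"]
        if g.symbol:
            parts.append(f"Name={g.symbol}")
        if g.biotype:
            parts.append(f"gene_biotype={g.biotype}")
        return ";".join(parts)
    if which == "mRNA":
        return f"ID=rna-{uid};Parent=gene-{uid}"
    return f"ID={which.lower()}-{uid}-{idx};Parent=rna-{uid}"


def write_gff3(aset: AnnotationSet, path: str) -> None:
    """Serialize the stored gene/exon/CDS model back to GFF3.

    Only the fields the model stores survive; one synthetic mRNA per gene
    carries the exon/CDS children. Feature IDs are unique even when a gene
    ID recurs on several sequences (alt-loci copies), so the parent chain
    resolves regardless of line order. Re-parsing reproduces the set.
    """
    seen: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if aset.assembly:
            fh.write(f"##genome-build {aset.assembly}\n")
        for g in aset.genes:
            n = seen.get(g.gene_id, 0)
            seen[g.gene_id] = n + 1
            uid = g.gene_id if n == 0 else f"{g.gene_id}.copy{n}"
            s = g.span
            row = [s.chrom, "annoverlap", "gene", str(s.start), str(s.end), ".", s.strand, "."]
            fh.write("\t".join(row + [_gff3_attrs(g, uid, "gene")]) + "\n")
            if g.exons or g.cds:
                row[2] = "mRNA"
                fh.write("\t".join(row + [_gff3_attrs(g, uid, "mRNA")]) + "\n")
            for i, iv in enumerate(g.exons):
                cols = [iv.chrom, "annoverlap", "exon", str(iv.start), str(iv.end), ".", iv.strand, "."]
                fh.write("\t".join(cols + [_gff3_attrs(g, uid, "exon", i)]) + "\n")
            for i, iv in enumerate(g.cds):
                cols = [iv.chrom, "annoverlap", "CDS", str(iv.start), str(iv.end), ".", iv.strand, "0"]
                fh.write("\t".join(cols + [_gff3_attrs(g, uid, "CDS", i)]) + "\n")


def _gtf_attrs(g: GeneModel, with_tx: bool) -> str:
    parts = [f'gene_id "{g.gene_id}";']
    if with_tx:
        parts.append(f'transcript_id "{g.gene_id}.t1";')
    if g.symbol:
        parts.append(f'gene_name "{g.symbol}";')
    if g.biotype:
        parts.append(f'gene_biotype "{g.biotype}";')
    return " ".join(parts)


def write_gtf(aset: AnnotationSet, path: str) -> None:
    """Serialize to GTF (gene + one transcript carrying exons/CDS)."""
    with open(path, "w") as fh:
        if aset.assembly:
            fh.write(f"#!genome-build {aset.assembly}\n")
        for g in aset.genes:
            s = g.span
            row = [s.chrom, "annoverlap", "gene", str(s.start), str(s.end), ".", s.strand, "."]
            fh.write("\t".join(row + [_gtf_attrs(g, with_tx=False)]) + "\n")
            if g.exons or g.cds:
                row[2] = "transcript"
                fh.write("\t".join(row + [_gtf_attrs(g, with_tx=True)]) + "\n")
            for iv in g.exons:
                cols = [iv.chrom, "annoverlap", "exon", str(iv.start), str(iv.end), ".", iv.strand, "."]
                fh.write("\t".join(cols + [_gtf_attrs(g, with_tx=True)]) + "\n")
            for iv in g.cds:
                cols = [iv.chrom, "annoverlap", "CDS", str(iv.start), str(iv.end), ".", iv.strand, "0"]
                fh.write("\t".join(cols + [_gtf_attrs(g, with_tx=True)]) + "\n")
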
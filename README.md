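# annoverlap

Position-based reconciliation of NCBI and Ensembl gene annotation, and
assembly of cross-species homolog tables from three independent evidence
sources.

## The problem

NCBI and Ensembl annotate the same genome assemblies with independent
pipelines, so the same physical gene usually exists twice: once under an
Entrez Gene ID and once under an Ensembl stable ID, with no complete mapping
between the two. For livestock and other non-model mammals this breaks every
workflow that needs to move between the two ID spaces — most painfully
ortholog lookup and functional-enrichment analysis, where gene lists must be
translated to human IDs. `annoverlap` addresses both halves of the problem:

1. **ID reconciliation.** Because both annotations sit on the same assembly,
   corresponding genes occupy the same coordinates. The package pairs Entrez
   and Ensembl gene IDs purely from genomic overlap of their gene, exon and
   CDS intervals, producing a one-to-one `ensembl2entrezgene` lookup table.
2. **Homolog assembly.** Cross-species gene pairs are collected from three
   routes — identical official HGNC symbols in NCBI `gene_info` tables,
   Ensembl Compara homology dumps (translated to Entrez IDs through the
   lookup table), and best-hit filtered BLASTn results between transcript
   sets — and merged into one evidence-annotated homolog table.

## The pairing algorithm

For an NCBI gene *n* and an Ensembl gene *e* on the same chromosome with
overlap width *w* = |span(*n*) ∩ span(*e*)| ≥ 1, the gene-level score is

    f(n, e) = w / min(width(n), width(e))

and the decision proceeds in three steps plus a duplicate filter:

1. **Pre-filter.** If neither span contains the other (a *protruding*
   overlap) and f < 0.25, the pair is dismissed.
2. **Direct acceptance.** If f > 0.50 the pair is accepted.
3. **Feature rescue.** Otherwise, for each feature type (exon, CDS) the mean
   over all overlapping element pairs (a, b) of
   inner(a, b) / outer(a, b) — intersection width over union-envelope
   width — is computed; the pair is accepted if either mean exceeds 0.50.
   A gene without features of a type contributes no mean there (absent, not
   zero), so genes annotated only with CDS can still be paired.
4. **Duplicate filter.** Any ID matched to several partners keeps only its
   best pair (gene fraction, then feature fraction, then lexicographic
   partner ID), iterated until the table is one-to-one in both columns.
   This resolves tandem clusters of similar genes (e.g. the protocadherin
   gamma cluster) without cross-assignments.

All cut-offs are strict inequalities and configurable (`AorParams`).

## Worked example

The package ships a deterministic scenario generator that plants gene
correspondences — including the hard cases: protruding overlaps on both
sides of the cut-off, split genes, exon-sharing clusters, alternative-locus
duplicates, exon-less genes — together with a truth table:

```
$ annoverlap simulate --seed 17 --out demo
$ annoverlap overlap --ncbi-gff3 demo/ncbi.gff3 --ensembl-gtf demo/ensembl.gtf --out demo/aor
160 ID pairs from 225 candidates (74.4% NCBI, 71.1% Ensembl assigned)
```

The scenario contains 215 NCBI genes (plus 10 alternative-locus duplicates)
and 225 Ensembl genes; 225 candidate pairs overlap by at least one base, and
the filters validate exactly the 160 planted correspondences — the decoys,
sub-threshold overlaps and exon-less partners are all refused, and the
duplicate filter keeps split-gene and cluster assignments one-to-one.
The lookup table records each pair's evidence:

```
$ head -4 demo/aor/ensembl2entrezgene.tsv
ensembl_id         entrez_id  gene_overlap_frac  evidence_frac  decision
ENSTST00000100001  100001     1.000000           1.000000       direct_positive
ENSTST00000100002  100002     1.000000           1.000000       direct_positive
ENSTST00000100003  100003     1.000000           1.000000       direct_positive
```

Symbol matching on the generated two-species `gene_info` table (10 official
symbols per species, 8 shared, one QTL collision and one type-`unknown`
record planted):

```
$ annoverlap symbols --gene-info demo/gene_info.tsv --taxids 9606,9823 --out demo/sym
8 symbol pairs across 2 species
$ cat demo/sym/match_matrix.tsv
        9606   9823
9606    100.0  80.0
9823    80.0   100.0
```

80% of either species' official symbols match the other — exactly the
planted 8/10; the QTL record whose symbol collides with a real gene symbol
is filtered out rather than producing a ninth, false pair.

Downstream, `annoverlap compara`, `annoverlap blast-filter` and
`annoverlap merge` attach Entrez IDs to Compara homologies, reduce BLAST
output to best-hit gene pairs, and union the three evidence sources into a
homolog table with per-source Venn counts; `annoverlap translate` converts
ID lists through the lookup table in either direction.

## Layout

- `annoverlap.annotation_io` — GFF3/GTF parsing (via gffutils), assembly
  check, chromosome aliasing, alternative-locus deduplication
- `annoverlap.overlap` — the pairing algorithm and its statistics
- `annoverlap.symbols` — gene_info loading, QTL filter, symbol matching
- `annoverlap.compara` — Compara dump filtering, the 12-column
  `all_ortholog` table
- `annoverlap.blast` — BLAST tabular filtering and gene-level aggregation
- `annoverlap.merge` — evidence union, Venn accounting, one-to-many filter,
  ID translation
- `annoverlap.simulate` — the scenario generators with truth tables
- `annoverlap.cli` — the `annoverlap` command

See `docs/methods.md` for the modelling decisions and their rationale.
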
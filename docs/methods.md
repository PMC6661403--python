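# Methods

## Coordinate model

All intervals are stored 1-based and inclusive on both ends, exactly as
GFF3/GTF represent them on disk; widths are `end − start + 1` throughout.
No half-open conversion happens anywhere except at the boundary to the
interval-tree index used for the candidate search (which is converted back
immediately). This removes the most common class of off-by-one errors in
annotation comparison.

A gene is reduced to its span plus flattened exon and CDS interval lists.
Identical intervals repeated by several transcript isoforms are collapsed,
so element-wise overlap means are not weighted by isoform count. Transcript
structure beyond that is deliberately not modelled: the pairing operates on
genes, exons and CDS only.

## Input harmonization

NCBI GFF3 and Ensembl GTF differ mainly in the attributes column. Entrez
IDs are taken from `Dbxref=GeneID:` first, then from a `gene_id` attribute;
Ensembl stable IDs from `gene_id`. When a GTF carries no explicit gene
lines, the gene span is the envelope of its exons. Parsing is delegated to
gffutils; a validation pre-pass reports malformed lines with line numbers,
which gffutils does not surface.

Two pre-conditions are enforced before any comparison:

* **Identical assembly.** Positions on different assemblies are not
  comparable; a label mismatch is a hard error, not a warning.
* **Unique gene IDs.** NCBI files occasionally repeat an Entrez ID on the
  primary assembly and on an alternative-locus scaffold (`NT_`/`NW_`
  prefixes). Harmonization keeps the primary-assembly copy (falling back to
  the longest span, then the lexicographically smallest sequence name) and
  records the dropped copies in a skip report.

Chromosome naming between the two sources is reconciled through an alias
map (two-column TSV; a canonical value of `.` drops the sequence). The
package ships a minimal default map (`chrN` → `N`, mitochondrial synonyms →
`MT`); nothing is guessed beyond it, because naming conventions vary too
much between assemblies to infer silently.

## The pairing decision

Scores and rules are described in the README. Decisions that were genuinely
open and how they were settled:

* **Strand is ignored by default.** The gene-level overlap search is
  position-driven; requiring strand agreement is available
  (`strand_mode="require_same"`) but off by default, since annotation
  pipelines occasionally disagree on the strand of poorly supported genes.
* **Strict boundaries.** "Below 25%" dismisses and "above 50%" accepts as
  strict inequalities: a protruding overlap of exactly 25% survives the
  pre-filter, a gene or feature overlap of exactly 50% is not accepted.
* **Element means.** The exon and CDS means are computed separately and
  tested disjunctively (exon OR CDS above the cut-off). Each mean averages
  inner/outer ratios over element pairs overlapping by at least one base
  (`min_feature_overlap_bases`); the outer width of an element pair is the
  union envelope `max(end) − min(start) + 1`. Non-overlapping element pairs
  are excluded rather than averaged in as zeros, and a gene without features
  of a type yields an *absent* mean, never zero — an undefined quantity must
  not act as evidence against a pair. Consequently exon-less gene pairs can
  still be validated through CDS and vice versa; genes lacking both can only
  be accepted directly at the gene level.
* **Candidates dismissed by the pre-filter never re-enter** via feature
  rescue; the rescue step sees only the surviving undecided candidates.
* **Duplicate filter.** "Best hit" is made a total order: gene fraction,
  then best feature mean, then lexicographically smaller partner ID. The
  filter repeatedly drops every accepted pair that is not the best for at
  least one of its two endpoints, to a fixed point. At the fixed point every
  surviving pair is mutually best, which makes the lookup table one-to-one
  in both columns — the strongest reading of duplicate removal, chosen
  because one-to-many ID assignments are precisely what bias downstream
  enrichment analyses.

Reported statistics: `n_overlaps` counts all candidates with ≥ 1 base of
overlap; `n_validated` counts candidates accepted by the filters *before*
the duplicate filter (this is the quantity that is provably monotone in the
thresholds); `n_pairs` and the per-source assignment percentages describe
the final one-to-one table.

## Symbol matching

`gene_info` records are dropped entirely when `type_of_gene` is `unknown`.
A record counts as *official* when its symbol is not a provisional
locus-number name (`LOC\d+`) and, where the dialect carries a
`Nomenclature_status` column, that column marks it official (`O`); official
records use the nomenclature-authority symbol when present. QTL records —
whose names can collide with genuine gene symbols — are removed when the
type or description contains the token `QTL` at a word boundary. Symbols
are compared case-insensitively (mouse `Tp53` must match human `TP53`) but
reported as stored. Each species is collapsed on symbol first; symbols with
several gene IDs emit the full cross-product flagged one-to-many, leaving
resolution to the merge stage. Synonym/alias matching is deliberately not
attempted.

## Compara and BLAST evidence

The Compara reader joins the `genome_db`, `gene_member`, `homology` and
`homology_member` dump tables, keeps pairwise homologies whose two members
both belong to the configured species, and preserves the homology class
string verbatim. All ortholog *and* paralog classes are kept by default
(an allowlist is available): the sequence-similarity routes intentionally
also deliver paralogs when no ortholog exists. Real dumps vary by release;
the consumed column subset is pinned and documented in the module.

BLAST tabular input (outfmt 6 plus `qcovs`; column order configurable) is
filtered for minimum bit score and query coverage (package defaults 50 bits
and 70% — conventional screening values, exposed as configuration), reduced
to one best hit per query transcript (bit score, then percent identity,
then lexicographic subject), and aggregated through transcript→gene maps
into gene pairs carrying the supporting-transcript count and maximum bit
score. Best hits are one-directional by default; an optional reciprocal
mode intersects the two directions. Running BLAST itself is out of scope —
the module consumes its output.

## Merging

The three evidence sets are unioned per (species, gene, species, gene) key;
no precedence exists among sources — disagreeing partners coexist, flagged
one-to-many. The Venn counts report exclusive regions and sum to the number
of distinct pairs. Two one-to-many policies are provided: `strict` removes
every member of a one-to-many group (the safe choice before enrichment
analysis, where a single gene matched to a whole histone family would
inflate each of that family's categories), and `best` keeps the record with
the largest evidence set (ties: BLAST support, then lexicographic key).

## Synthetic scenarios

The generator fabricates coordinates, never sequence; BLAST output is
fabricated rather than computed from sequences, and exon/CDS placement in
two of the case classes does not respect exon–CDS containment. What passing
tests therefore demonstrate is the correctness of the decision logic on
planted geometry — not robustness to real-world annotation noise such as
assembly patches, trans-spliced genes, or dialect quirks beyond the two
supported formats.

The standard scenario plants 215 NCBI genes (plus 10 alternative-locus
duplicate copies) and 225 Ensembl genes on three chromosomes: 60 identical
pairs, 25 protruding pairs between the 25% and 50% cut-offs rescued by a
shared exon, 20 protruding pairs below 25%, 25 contained pairs, 10 split
genes (one NCBI gene covering two Ensembl genes), 5 three-membered
exon-sharing clusters, 10 alternative-locus duplicates, 15 exon-less
partners, 15 CDS-only rescues and 20 non-overlapping decoys. Intergenic
gaps are drawn uniformly from 2–8 kb, large enough that cases cannot
interact. These counts keep every case class well represented while the
whole suite runs in seconds.

Expected decisions in the truth tables are computed by a naive oracle that
enumerates covered bases as explicit Python sets, kept independent of the
interval arithmetic under test; geometry that violates its case class makes
generation fail rather than emit a wrong truth. All randomness flows from a
single integer seed; one seed yields byte-identical files.

## Numerical and determinism notes

Overlap fractions are exact integer ratios evaluated in double precision;
the boundary cases used in tests are chosen so the critical values (0.25,
0.5) are exactly representable. All output tables are canonically sorted
and fraction columns printed with six decimals, so identical inputs — under
any row permutation — produce byte-identical files. Every tie anywhere in
the package (duplicate filter, best hit, one-to-many `best` mode) is broken
by an explicit total order ending in lexicographic IDs.

## Known limitations

* Transcript isoforms are not modelled; pairing is strictly gene-level.
* Splice-site agreement (used by NCBI's own gene2ensembl procedure) is
  intentionally not a criterion.
* The Compara column subset is pinned to one dump schema.
* The default chromosome alias map covers only common conventions; unusual
  assemblies need a user-supplied map.
* One-to-many resolution is positional/evidence-based only; no sequence
  re-alignment is attempted to adjudicate conflicting partners.
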
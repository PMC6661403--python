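"""Position-based pairing of NCBI and Ensembl genes on a shared assembly.

Two annotation pipelines run on the same assembly place mostly the same genes
at mostly the same coordinates, but under different identifiers. This module
assigns Entrez ↔ Ensembl ID pairs purely from coordinate overlap, in three
filtering steps plus a duplicate filter:

1. *Gene level.* Every NCBI/Ensembl gene pair overlapping by at least one
   base becomes a candidate; its score is the overlap width divided by the
   width of the smaller gene. Protruding candidates (neither gene contained
   in the other) below 25% of the smaller gene are dismissed outright.
2. *Direct acceptance.* Candidates with a gene-level fraction strictly above
   50% are accepted without looking at features.
3. *Feature rescue.* Remaining candidates are scored by the mean, over all
   overlapping exon (respectively CDS) element pairs, of the element pair's
   inner width (intersection) over outer width (union envelope). A mean
   strictly above 50% on either feature type rescues the candidate; genes
   lacking a feature type contribute no mean there (absent, not zero), so a
   CDS-only gene can still rescue via CDS.

Finally a best-hit duplicate filter reduces the accepted pairs to a
one-to-one table: any ID matched to several partners keeps only its
best-scoring pair (gene fraction, then feature fraction, then lexicographic
partner ID), iterated to a fixed point. The result is the
``ensembl2entrezgene`` lookup table.

All cut-offs sit in :class:`AorParams`; the boundary semantics are strict as
stated above (exactly 25% survives the pre-filter, exactly 50% is *not* a
direct or rescued positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import AnnotationSet, GeneModel, GenomicInterval

# candidate decision states
DISMISSED_PREFILTER = "dismissed_prefilter"
DIRECT_POSITIVE = "direct_positive"
RESCUED_POSITIVE = "rescued_positive"
REJECTED = "rejected"
DROPPED_DUPLICATE = "dropped_duplicate"
UNDECIDED = "undecided"

POSITIVE_DECISIONS = frozenset({DIRECT_POSITIVE, RESCUED_POSITIVE})

# span topology
CONTAINED = "contained"
PROTRUDING = "protruding"
IDENTICAL = "identical"

STRAND_IGNORE = "ignore"
STRAND_REQUIRE_SAME = "require_same"


@dataclass(frozen=True)
class AorParams:
    """All thresholds of the pairing algorithm.

    min_protruding_frac
        Smaller-gene overlap fraction below which a *protruding* candidate is
        dismissed before any other step (default 0.25; strictly-below).
    direct_accept_frac
        Gene-level fraction strictly above which a candidate is accepted
        directly (default 0.50).
    feature_accept_frac
        Mean exon or CDS inner/outer ratio strictly above which an undecided
        candidate is rescued (default 0.50).
    min_feature_overlap_bases
        Minimum element-pair overlap for an exon/CDS pair to enter the mean
        (default 1 base).
    strand_mode
        ``ignore`` (default): overlap on coordinates only, matching the
        position-driven gene-level search. ``require_same``: genes and
        elements on opposite strands never overlap.
    """

    min_protruding_frac: float = 0.25
    direct_accept_frac: float = 0.50
    feature_accept_frac: float = 0.50
    min_feature_overlap_bases: int = 1
    strand_mode: str = STRAND_IGNORE

    def __post_init__(self) -> None:
        for name in ("min_protruding_frac", "direct_accept_frac", "feature_accept_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_feature_overlap_bases < 1:
            raise ValueError("min_feature_overlap_bases must be >= 1")
        if self.strand_mode not in (STRAND_IGNORE, STRAND_REQUIRE_SAME):
            raise ValueError(f"unknown strand_mode {self.strand_mode!r}")


@dataclass
class OverlapCandidate:
    """One NCBI/Ensembl gene pair under consideration, with its scores."""

    ncbi_id: str
    ensembl_id: str
    gene_overlap_frac: float
    overlap_width: int
    topology: str
    exon_mean_overlap: Optional[float] = None
    cds_mean_overlap: Optional[float] = None
    decision: str = UNDECIDED

    @property
    def feature_best(self) -> float:
        """Best available feature mean; -1 when neither is defined."""
        vals = [v for v in (self.exon_mean_overlap, self.cds_mean_overlap) if v is not None]
        return max(vals) if vals else -1.0


@dataclass(frozen=True)
class IdPair:
    """One validated Entrez ↔ Ensembl correspondence (a lookup-table row)."""

    ncbi_id: str
    ensembl_id: str
    gene_overlap_frac: float
    evidence_frac: float
    decision: str


@dataclass
class AssignmentStats:
    """Table-style summary of one pairing run."""

    n_ncbi_genes: int
    n_ensembl_genes: int
    n_overlaps: int
    n_validated: int
    n_pairs: int
    pct_ncbi_assigned: float
    pct_ensembl_assigned: float


def _strands_compatible(a: GenomicInterval, b: GenomicInterval, strand_mode: str) -> bool:
    if strand_mode != STRAND_REQUIRE_SAME:
        return True
    return a.strand == b.strand or "." in (a.strand, b.strand)


def interval_overlap_width(
    a: GenomicInterval, b: GenomicInterval, strand_mode: str = STRAND_IGNORE
) -> int:
    """Number of bases covered by both intervals (0 off-chromosome)."""
    if a.chrom != b.chrom or not _strands_compatible(a, b, strand_mode):
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def inner_outer_widths(a: GenomicInterval, b: GenomicInterval) -> tuple[int, int]:
    """(intersection width, union-envelope width) of two same-chrom intervals.

    The outer width is the envelope ``max(end) - min(start) + 1`` — for two
    disjoint intervals it includes the gap, which only makes the ratio
    smaller (such pairs are excluded from the means anyway).
    """
    if a.chrom != b.chrom:
        raise ValueError("inner/outer widths need intervals on one chromosome")
    inner = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    outer = max(a.end, b.end) - min(a.start, b.start) + 1
    return inner, outer


def _topology(a: GenomicInterval, b: GenomicInterval) -> str:
    if a.start == b.start and a.end == b.end:
        return IDENTICAL
    if (a.start <= b.start and b.end <= a.end) or (b.start <= a.start and a.end <= b.end):
        return CONTAINED
    return PROTRUDING


def find_gene_overlaps(
    ncbi: AnnotationSet, ensembl: AnnotationSet, params: AorParams
) -> list[OverlapCandidate]:
    """All NCBI/Ensembl gene pairs overlapping by at least one base.

    The fraction is overlap width over the width of the *smaller* gene, so a
    gene fully contained in a larger partner always scores 1.0.
    """
    trees: dict[str, IntervalTree] = {}
    ens_genes: dict[str, GeneModel] = {}
    for g in ensembl.genes:
        # IntervalTree is half-open; +1 converts the inclusive end.
        trees.setdefault(g.chrom, IntervalTree()).addi(g.span.start, g.span.end + 1, g.gene_id)
        ens_genes[g.gene_id] = g
    out: list[OverlapCandidate] = []
    for ng in ncbi.genes:
        tree = trees.get(ng.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(ng.span.start, ng.span.end + 1):
            eg = ens_genes[hit.data]
            width = interval_overlap_width(ng.span, eg.span, params.strand_mode)
            if width < 1:
                continue
            smaller = min(ng.span.width, eg.span.width)
            out.append(
                OverlapCandidate(
                    ncbi_id=ng.gene_id,
                    ensembl_id=eg.gene_id,
                    gene_overlap_frac=width / smaller,
                    overlap_width=width,
                    topology=_topology(ng.span, eg.span),
                )
            )
    out.sort(key=lambda c: (c.ncbi_id, c.ensembl_id))
    return out


def prefilter_protruding(
    cands: Iterable[OverlapCandidate], params: AorParams
) -> list[OverlapCandidate]:
    """Dismiss protruding candidates below the smaller-gene cut-off.

    Contained and identical spans are never dismissed here (their fraction is
    1.0 by construction). Exactly at the cut-off the candidate survives:
    only overlaps strictly below it are dismissed.
    """
    out = []
    for c in cands:
        if c.topology == PROTRUDING and c.gene_overlap_frac < params.min_protruding_frac:
            c = replace(c, decision=DISMISSED_PREFILTER)
        out.append(c)
    return out


def classify_direct(
    cands: Iterable[OverlapCandidate], params: AorParams
) -> list[OverlapCandidate]:
    """Accept candidates whose gene-level fraction is strictly above the cut."""
    out = []
    for c in cands:
        if c.decision == UNDECIDED and c.gene_overlap_frac > params.direct_accept_frac:
            c = replace(c, decision=DIRECT_POSITIVE)
        out.append(c)
    return out


def mean_feature_overlap(
    gene_a: GeneModel,
    gene_b: GeneModel,
    feature: str,
    params: AorParams = AorParams(),
) -> Optional[float]:
    """Mean inner/outer ratio over overlapping exon or CDS element pairs.

    Returns ``None`` — not 0 — when either gene has no features of the
    requested type or no element pair overlaps by at least
    ``min_feature_overlap_bases``: an undefined mean must not masquerade as
    evidence against the pair.
    """
    if feature == "exon":
        feats_a, feats_b = gene_a.exons, gene_b.exons
    elif feature == "cds":
        feats_a, feats_b = gene_a.cds, gene_b.cds
    else:
        raise ValueError(f"feature must be 'exon' or 'cds', got {feature!r}")
    if not feats_a or not feats_b:
        return None
    ratios: list[float] = []
    for fa in feats_a:
        for fb in feats_b:
            if not _strands_compatible(fa, fb, params.strand_mode):
                continue
            inner, outer = inner_outer_widths(fa, fb)
            if inner >= params.min_feature_overlap_bases:
                ratios.append(inner / outer)
    if not ratios:
        return None
    return sum(ratios) / len(ratios)


def _attach_feature_means(
    cands: list[OverlapCandidate],
    ncbi_by_id: dict[str, GeneModel],
    ens_by_id: dict[str, GeneModel],
    params: AorParams,
) -> list[OverlapCandidate]:
    out = []
    for c in cands:
        if c.decision == DISMISSED_PREFILTER:
            out.append(c)
            continue
        ng, eg = ncbi_by_id[c.ncbi_id], ens_by_id[c.ensembl_id]
        out.append(
            replace(
                c,
                exon_mean_overlap=mean_feature_overlap(ng, eg, "exon", params),
                cds_mean_overlap=mean_feature_overlap(ng, eg, "cds", params),
            )
        )
    return out


def rescue_by_features(
    cands: Iterable[OverlapCandidate], params: AorParams
) -> list[OverlapCandidate]:
    """Decide the remaining candidates on exon/CDS evidence.

    Rescued when either feature mean is strictly above the cut-off; absent
    means never satisfy the test. Everything else is rejected.
    """
    out = []
    for c in cands:
        if c.decision != UNDECIDED:
            out.append(c)
            continue
        exon_ok = c.exon_mean_overlap is not None and c.exon_mean_overlap > params.feature_accept_frac
        cds_ok = c.cds_mean_overlap is not None and c.cds_mean_overlap > params.feature_accept_frac
        out.append(replace(c, decision=RESCUED_POSITIVE if (exon_ok or cds_ok) else REJECTED))
    return out


def _pair_score(c: OverlapCandidate) -> tuple[float, float]:
    return (c.gene_overlap_frac, c.feature_best)


def deduplicate(positives: list[OverlapCandidate]) -> tuple[list[IdPair], list[OverlapCandidate]]:
    """Best-hit duplicate filter: reduce accepted pairs to a one-to-one table.

    Iteratively drops every pair that is not the best for at least one of its
    two endpoints (gene fraction, then feature fraction, then
    lexicographically smaller partner ID), until each surviving pair is
    mutually best — which makes both ID columns duplicate-free. Dropped
    candidates are returned re-labelled ``dropped_duplicate``.
    """
    for c in positives:
        if c.decision not in POSITIVE_DECISIONS:
            raise ValueError(f"deduplicate expects positives, got {c.decision}")
    alive = list(positives)
    while True:
        best_n: dict[str, OverlapCandidate] = {}
        best_e: dict[str, OverlapCandidate] = {}
        for c in alive:
            cur = best_n.get(c.ncbi_id)
            if cur is None or (_pair_score(c), _rev(c.ensembl_id)) > (_pair_score(cur), _rev(cur.ensembl_id)):
                best_n[c.ncbi_id] = c
            cur = best_e.get(c.ensembl_id)
            if cur is None or (_pair_score(c), _rev(c.ncbi_id)) > (_pair_score(cur), _rev(cur.ncbi_id)):
                best_e[c.ensembl_id] = c
        survivors = [c for c in alive if best_n[c.ncbi_id] is c and best_e[c.ensembl_id] is c]
        if len(survivors) == len(alive):
            break
        alive = survivors
    kept_keys = {(c.ncbi_id, c.ensembl_id) for c in alive}
    dropped = [
        replace(c, decision=DROPPED_DUPLICATE)
        for c in positives
        if (c.ncbi_id, c.ensembl_id) not in kept_keys
    ]
    pairs = [
        IdPair(
            ncbi_id=c.ncbi_id,
            ensembl_id=c.ensembl_id,
            gene_overlap_frac=c.gene_overlap_frac,
            evidence_frac=c.gene_overlap_frac if c.decision == DIRECT_POSITIVE else c.feature_best,
            decision=c.decision,
        )
        for c in alive
    ]
    pairs.sort(key=lambda p: (p.ncbi_id, p.ensembl_id))
    return pairs, dropped


class _Rev:
    """Wrapper inverting string order so max() prefers the smaller ID."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_Rev") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_Rev") -> bool:
        return self.s < other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Rev) and self.s == other.s


def _rev(s: str) -> _Rev:
    return _Rev(s)


def run_overlap_pipeline(
    ncbi: AnnotationSet, ensembl: AnnotationSet, params: AorParams = AorParams()
) -> tuple[list[IdPair], list[OverlapCandidate], AssignmentStats]:
    """Run the full pairing: candidates → pre-filter → direct → rescue → dedup.

    Returns the one-to-one lookup table, the full candidate ledger (every
    pair ever considered, with its final decision) for audit, and summary
    statistics. ``n_validated`` counts candidates accepted by the filters
    *before* the duplicate filter; the assignment percentages count unique
    IDs in the final table against the per-source gene totals.
    """
    ncbi_by_id = ncbi.by_id()
    ens_by_id = ensembl.by_id()
    cands = find_gene_overlaps(ncbi, ensembl, params)
    cands = prefilter_protruding(cands, params)
    cands = classify_direct(cands, params)
    cands = _attach_feature_means(cands, ncbi_by_id, ens_by_id, params)
    cands = rescue_by_features(cands, params)
    positives = [c for c in cands if c.decision in POSITIVE_DECISIONS]
    pairs, dropped = deduplicate(positives)
    dropped_keys = {(c.ncbi_id, c.ensembl_id) for c in dropped}
    ledger = [
        replace(c, decision=DROPPED_DUPLICATE)
        if (c.ncbi_id, c.ensembl_id) in dropped_keys
        else c
        for c in cands
    ]
    n_ncbi, n_ens = len(ncbi.genes), len(ensembl.genes)
    if n_ncbi == 0 or n_ens == 0:
        warnings.warn("one annotation set is empty; assignment percentages reported as 0")
    stats = AssignmentStats(
        n_ncbi_genes=n_ncbi,
        n_ensembl_genes=n_ens,
        n_overlaps=len(cands),
        n_validated=len(positives),
        n_pairs=len(pairs),
        pct_ncbi_assigned=(100.0 * len({p.ncbi_id for p in pairs}) / n_ncbi) if n_ncbi else 0.0,
        pct_ensembl_assigned=(100.0 * len({p.ensembl_id for p in pairs}) / n_ens) if n_ens else 0.0,
    )
    return pairs, ledger, stats
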
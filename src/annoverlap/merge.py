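"""Merging symbol, Compara and BLAST evidence into one homolog table.

Each of the three assignment routes produces cross-species gene pairs in
Entrez IDs (Compara pairs are translated through the position-based lookup
first). The merger unions them, records which sources support each pair,
counts the Venn regions of the three evidence sets, and offers the
one-to-many filter needed before functional-enrichment analysis — a single
gene matched to a whole family (the histone case) otherwise inflates every
category that family sits in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .blast import GenePair
from .overlap import IdPair
from .symbols import SymbolPair

EVIDENCE_SYMBOL = "symbol"
EVIDENCE_COMPARA = "compara"
EVIDENCE_BLAST = "blast"

VENN_REGIONS = [
    "symbol",
    "compara",
    "blast",
    "symbol+compara",
    "symbol+blast",
    "compara+blast",
    "symbol+compara+blast",
]

MODE_STRICT = "strict"
MODE_BEST = "best"


@dataclass
class HomologRecord:
    """One cross-species gene pair with its evidence and scores."""

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    evidence: frozenset = field(default_factory=frozenset)
    symbol: str = ""
    compara_type: str = ""
    blast_support: int = 0
    blast_bitscore: float = 0.0
    one_to_many: bool = False

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.species_a, self.gene_a, self.species_b, self.gene_b)


def merge_sources(
    symbol_pairs: Iterable[SymbolPair],
    compara_pairs: Iterable[tuple[str, str, str, str, str]],
    blast_pairs: Iterable[GenePair],
    species_a: str = "a",
    species_b: str = "b",
) -> tuple[list[HomologRecord], dict[str, int]]:
    """Union the three evidence sets into per-pair records plus Venn counts.

    Pairs are keyed by (species, gene) on both sides; evidence sets merge,
    scores are carried from whichever source provides them. The Venn dict
    counts pairs per exclusive region (single-source, each pairwise-only
    region, all three) and sums to the number of distinct pairs. The merge
    is idempotent and does not depend on input order.
    """
    records: dict[tuple[str, str, str, str], HomologRecord] = {}

    def rec(key: tuple[str, str, str, str]) -> HomologRecord:
        if key not in records:
            records[key] = HomologRecord(
                species_a=key[0], gene_a=key[1], species_b=key[2], gene_b=key[3]
            )
        return records[key]

    for sp in symbol_pairs:
        r = rec((species_a, sp.entrez_a, species_b, sp.entrez_b))
        r.evidence = r.evidence | {EVIDENCE_SYMBOL}
        r.symbol = sp.symbol
        r.one_to_many = r.one_to_many or sp.one_to_many
    for (sa, ga, sb, gb, otype) in compara_pairs:
        r = rec((sa, ga, sb, gb))
        r.evidence = r.evidence | {EVIDENCE_COMPARA}
        r.compara_type = otype
    for bp in blast_pairs:
        r = rec((species_a, bp.gene_query, species_b, bp.gene_subject))
        r.evidence = r.evidence | {EVIDENCE_BLAST}
        r.blast_support = bp.support_count
        r.blast_bitscore = bp.max_bitscore
        r.one_to_many = r.one_to_many or bp.one_to_many
    merged = sorted(records.values(), key=lambda r: r.key)
    _flag_one_to_many(merged)
    venn = {region: 0 for region in VENN_REGIONS}
    for r in merged:
        venn["+".join(e for e in (EVIDENCE_SYMBOL, EVIDENCE_COMPARA, EVIDENCE_BLAST) if e in r.evidence)] += 1
    return merged, venn


def _flag_one_to_many(records: list[HomologRecord]) -> None:
    """Flag every record whose gene (either side) has several partners."""
    count_a: dict[tuple[str, str], int] = {}
    count_b: dict[tuple[str, str], int] = {}
    for r in records:
        count_a[(r.species_a, r.gene_a)] = count_a.get((r.species_a, r.gene_a), 0) + 1
        count_b[(r.species_b, r.gene_b)] = count_b.get((r.species_b, r.gene_b), 0) + 1
    for r in records:
        if count_a[(r.species_a, r.gene_a)] > 1 or count_b[(r.species_b, r.gene_b)] > 1:
            r.one_to_many = True


def filter_one_to_many(records: Sequence[HomologRecord], mode: str = MODE_STRICT) -> list[HomologRecord]:
    """Resolve genes matched to several partners.

    ``strict`` keeps only genes with exactly one partner on both sides —
    every member of a one-to-many group is removed (the safe choice before
    enrichment analysis). ``best`` keeps, per many-sided gene, the record
    with the largest evidence set, ties broken by higher BLAST support, then
    by lexicographically smaller partner key.
    """
    if mode not in (MODE_STRICT, MODE_BEST):
        raise ValueError(f"unknown mode {mode!r}")
    count_a: dict[tuple[str, str], int] = {}
    count_b: dict[tuple[str, str], int] = {}
    for r in records:
        count_a[(r.species_a, r.gene_a)] = count_a.get((r.species_a, r.gene_a), 0) + 1
        count_b[(r.species_b, r.gene_b)] = count_b.get((r.species_b, r.gene_b), 0) + 1
    if mode == MODE_STRICT:
        return [
            r
            for r in records
            if count_a[(r.species_a, r.gene_a)] == 1 and count_b[(r.species_b, r.gene_b)] == 1
        ]
    # best: iterate the same mutual-best reduction used by the ID dedup
    alive = list(records)
    while True:
        best_a: dict[tuple[str, str], HomologRecord] = {}
        best_b: dict[tuple[str, str], HomologRecord] = {}
        for r in alive:
            ka, kb = (r.species_a, r.gene_a), (r.species_b, r.gene_b)
            if ka not in best_a or _record_rank(r) > _record_rank(best_a[ka]):
                best_a[ka] = r
            if kb not in best_b or _record_rank(r) > _record_rank(best_b[kb]):
                best_b[kb] = r
        survivors = [
            r
            for r in alive
            if best_a[(r.species_a, r.gene_a)] is r and best_b[(r.species_b, r.gene_b)] is r
        ]
        if len(survivors) == len(alive):
            return survivors
        alive = survivors


def _record_rank(r: HomologRecord) -> tuple:
    return (len(r.evidence), r.blast_support, [-ord(c) for c in "\x00".join(r.key)])


DIRECTION_NCBI2ENSEMBL = "ncbi2ensembl"
DIRECTION_ENSEMBL2NCBI = "ensembl2ncbi"


def translate_ids(
    gene_ids: Sequence[str],
    direction: str,
    lookup: Iterable[IdPair],
) -> tuple[list[Optional[str]], list[str]]:
    """Translate gene IDs through the one-to-one lookup table.

    Output order preserves input order (``None`` where unmapped); duplicates
    translate to duplicates. The second return value lists the unmapped
    inputs in input order.
    """
    if direction == DIRECTION_NCBI2ENSEMBL:
        table = {p.ncbi_id: p.ensembl_id for p in lookup}
    elif direction == DIRECTION_ENSEMBL2NCBI:
        table = {p.ensembl_id: p.ncbi_id for p in lookup}
    else:
        raise ValueError(f"direction must be {DIRECTION_NCBI2ENSEMBL} or {DIRECTION_ENSEMBL2NCBI}")
    translated = [table.get(g) for g in gene_ids]
    unmapped = [g for g, t in zip(gene_ids, translated) if t is None]
    return translated, unmapped
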
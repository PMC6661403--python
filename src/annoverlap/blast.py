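"""Filtering pairwise BLASTn output down to gene-level homolog pairs.

Sequence similarity catches homologs the symbol and Compara routes miss —
notably non-coding genes. The input is tabular BLASTn output (outfmt-6
style) from aligning one species' transcript set against another's; it is
filtered for a minimal bit score and query coverage, reduced to the best hit
per query transcript (by bit score), and aggregated through
transcript → gene maps into gene pairs, since annotation carries several
transcript sequences per gene.

The bit-score and coverage thresholds are this package's configuration
defaults (50 bits, 70%), chosen as conventional homology-screen values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import AnnotationParseError

#: Default column layout: standard outfmt 6 plus a trailing qcovs column
#: (``-outfmt "6 std qcovs"``).
DEFAULT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore qcovs"
).split()

DEFAULT_MIN_BITSCORE = 50.0
DEFAULT_MIN_QCOV = 70.0


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bit_score: float
    e_value: float
    query_coverage: float


@dataclass(frozen=True)
class GenePair:
    """A gene-level homolog pair aggregated from best transcript hits."""

    gene_query: str
    gene_subject: str
    support_count: int
    max_bitscore: float
    one_to_many: bool


def parse_blast_tab(
    path: str, columns: Sequence[str] = DEFAULT_COLUMNS
) -> tuple[list[BlastHit], int]:
    """Read tabular BLAST output; malformed rows are dropped and counted."""
    needed = {"qseqid", "sseqid", "pident", "length", "evalue", "bitscore", "qcovs"}
    missing = needed - set(columns)
    if missing:
        raise AnnotationParseError(f"column layout lacks required fields: {sorted(missing)}")
    idx = {name: i for i, name in enumerate(columns)}
    hits: list[BlastHit] = []
    rejected = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != len(columns):
                rejected += 1
                continue
            try:
                hits.append(
                    BlastHit(
                        query_id=cols[idx["qseqid"]],
                        subject_id=cols[idx["sseqid"]],
                        percent_identity=float(cols[idx["pident"]]),
                        alignment_length=int(cols[idx["length"]]),
                        bit_score=float(cols[idx["bitscore"]]),
                        e_value=float(cols[idx["evalue"]]),
                        query_coverage=float(cols[idx["qcovs"]]),
                    )
                )
            except ValueError:
                rejected += 1
    return hits, rejected


def filter_hits(
    hits: Iterable[BlastHit],
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    min_qcov: float = DEFAULT_MIN_QCOV,
) -> list[BlastHit]:
    """Keep hits meeting both the bit-score and query-coverage minimum."""
    return [h for h in hits if h.bit_score >= min_bitscore and h.query_coverage >= min_qcov]


def best_hit_per_query(hits: Iterable[BlastHit]) -> list[BlastHit]:
    """Exactly one hit per query: highest bit score, ties by higher percent
    identity, then lexicographically smaller subject ID."""
    best: dict[str, BlastHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) > _hit_rank(cur):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


def _hit_rank(h: BlastHit) -> tuple:
    return (h.bit_score, h.percent_identity, [-ord(c) for c in h.subject_id])


def load_tx2gene(path: str) -> dict[str, str]:
    """Two-column TSV ``transcript<TAB>gene`` → dict (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise AnnotationParseError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and cols[0].lower() in ("transcript", "transcript_id", "tx"):
                continue
            out[cols[0]] = cols[1]
    return out


def hits_to_gene_pairs(
    best_hits: Iterable[BlastHit],
    tx2gene_query: Mapping[str, str],
    tx2gene_subject: Mapping[str, str],
) -> list[GenePair]:
    """Aggregate best transcript hits to deduplicated gene pairs.

    A pair backed by k query transcripts carries ``support_count=k`` and the
    maximum bit score among them. Query genes whose transcripts best-hit
    several subject genes have all their pairs flagged one-to-many. Every
    transcript must be present in its map.
    """
    agg: dict[tuple[str, str], list[BlastHit]] = {}
    for h in best_hits:
        if h.query_id not in tx2gene_query:
            raise KeyError(f"transcript {h.query_id!r} absent from query tx2gene map")
        if h.subject_id not in tx2gene_subject:
            raise KeyError(f"transcript {h.subject_id!r} absent from subject tx2gene map")
        key = (tx2gene_query[h.query_id], tx2gene_subject[h.subject_id])
        agg.setdefault(key, []).append(h)
    partners: dict[str, set[str]] = {}
    for gq, gs in agg:
        partners.setdefault(gq, set()).add(gs)
    pairs = [
        GenePair(
            gene_query=gq,
            gene_subject=gs,
            support_count=len(hs),
            max_bitscore=max(h.bit_score for h in hs),
            one_to_many=len(partners[gq]) > 1,
        )
        for (gq, gs), hs in agg.items()
    ]
    pairs.sort(key=lambda p: (p.gene_query, p.gene_subject))
    return pairs


def reciprocal_filter(
    pairs_ab: Iterable[GenePair], pairs_ba: Iterable[GenePair]
) -> list[GenePair]:
    """Keep A→B pairs whose gene pair also appears in the B→A direction."""
    back = {(p.gene_subject, p.gene_query) for p in pairs_ba}
    return [p for p in pairs_ab if (p.gene_query, p.gene_subject) in back]
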
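"""TSV serialization of the pipeline's tables.

All writers emit canonically sorted rows with fixed headers so that
identical inputs — in any row order — produce byte-identical files.
Fractions are printed with six decimals.
"""

from __future__ import annotations

import csv
from typing import Iterable, Optional, Sequence

from .merge import HomologRecord
from .overlap import AssignmentStats, IdPair, OverlapCandidate

LOOKUP_COLUMNS = ["ensembl_id", "entrez_id", "gene_overlap_frac", "evidence_frac", "decision"]
LEDGER_COLUMNS = [
    "ncbi_id",
    "ensembl_id",
    "gene_overlap_frac",
    "topology",
    "exon_mean_overlap",
    "cds_mean_overlap",
    "decision",
]
HOMOLOG_COLUMNS = [
    "species_a",
    "gene_a",
    "symbol",
    "species_b",
    "gene_b",
    "evidence",
    "compara_type",
    "blast_support",
    "blast_bitscore",
    "one_to_many",
]


def _frac(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.6f}"


def _writer(fh):
    return csv.writer(fh, delimiter="\t", lineterminator="\n")


def write_lookup_table(pairs: Iterable[IdPair], path: str) -> None:
    """The ensembl2entrezgene lookup table, sorted by Ensembl stable ID."""
    rows = sorted(pairs, key=lambda p: p.ensembl_id)
    with open(path, "w", newline="") as fh:
        w = _writer(fh)
        w.writerow(LOOKUP_COLUMNS)
        for p in rows:
            w.writerow([p.ensembl_id, p.ncbi_id, _frac(p.gene_overlap_frac), _frac(p.evidence_frac), p.decision])


def read_lookup_table(path: str) -> list[IdPair]:
    pairs = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pairs.append(
                IdPair(
                    ncbi_id=row["entrez_id"],
                    ensembl_id=row["ensembl_id"],
                    gene_overlap_frac=float(row["gene_overlap_frac"]),
                    evidence_frac=float(row["evidence_frac"]),
                    decision=row["decision"],
                )
            )
    return pairs


def write_candidate_ledger(cands: Iterable[OverlapCandidate], path: str) -> None:
    """Full audit trail: every considered pair with its final decision."""
    rows = sorted(cands, key=lambda c: (c.ncbi_id, c.ensembl_id))
    with open(path, "w", newline="") as fh:
        w = _writer(fh)
        w.writerow(LEDGER_COLUMNS)
        for c in rows:
            w.writerow(
                [
                    c.ncbi_id,
                    c.ensembl_id,
                    _frac(c.gene_overlap_frac),
                    c.topology,
                    _frac(c.exon_mean_overlap),
                    _frac(c.cds_mean_overlap),
                    c.decision,
                ]
            )


def write_homolog_table(records: Sequence[HomologRecord], path: str) -> None:
    rows = sorted(records, key=lambda r: r.key)
    with open(path, "w", newline="") as fh:
        w = _writer(fh)
        w.writerow(HOMOLOG_COLUMNS)
        for r in rows:
            w.writerow(
                [
                    r.species_a,
                    r.gene_a,
                    r.symbol,
                    r.species_b,
                    r.gene_b,
                    ",".join(sorted(r.evidence)),
                    r.compara_type,
                    r.blast_support,
                    _frac(r.blast_bitscore),
                    int(r.one_to_many),
                ]
            )


def stats_to_dict(stats: AssignmentStats) -> dict:
    return {
        "n_ncbi_genes": stats.n_ncbi_genes,
        "n_ensembl_genes": stats.n_ensembl_genes,
        "n_overlaps": stats.n_overlaps,
        "n_validated": stats.n_validated,
        "n_pairs": stats.n_pairs,
        "pct_ncbi_assigned": round(stats.pct_ncbi_assigned, 4),
        "pct_ensembl_assigned": round(stats.pct_ensembl_assigned, 4),
    }
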
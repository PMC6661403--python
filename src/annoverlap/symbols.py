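"""Cross-species ortholog assignment by identical official gene symbols.

HGNC symbols are reused across mammals for orthologous genes, so two records
carrying the same official symbol in different species are near-certain
orthologs. The inputs are NCBI ``gene_info``-format tables; the pitfalls this
module guards against are (a) provisional locus-number symbols
(``LOC100152218``-style) that carry no nomenclature information, (b) records
whose type of gene is ``unknown``, and (c) QTL records whose names collide
with genuine HGNC symbols.

Symbols are compared case-insensitively (mouse ``Tp53`` must match human
``TP53``) but reported as stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import AnnotationParseError, looks_like_loc_symbol, mentions_qtl

REQUIRED_COLUMNS = ["tax_id", "GeneID", "Symbol", "description", "type_of_gene"]
_NOMENCLATURE_SYMBOL = "Symbol_from_nomenclature_authority"
_NOMENCLATURE_STATUS = "Nomenclature_status"


@dataclass
class GeneInfoRecord:
    tax_id: int
    entrez_id: str
    symbol: str
    is_official: bool
    type_of_gene: str
    description: str


@dataclass
class SymbolPair:
    """Entrez IDs in two species joined on one shared official symbol."""

    entrez_a: str
    entrez_b: str
    symbol: str
    one_to_many: bool


@dataclass
class SymbolMatchMatrix:
    """Per-species totals and pairwise percent-matched table.

    ``matrix.loc[s, t]`` = percent of species s's official symbols also
    present (case-insensitively) in species t's official symbol set; the
    diagonal is 100 by construction.
    """

    taxids: list[int]
    n_genes: dict[int, int]
    n_official: dict[int, int]
    matrix: pd.DataFrame = field(repr=False)


def _record_is_official(row: pd.Series, has_status: bool) -> bool:
    symbol = str(row["Symbol"])
    if looks_like_loc_symbol(symbol):
        return False
    if has_status:
        status = str(row.get(_NOMENCLATURE_STATUS, "-"))
        if status != "-":
            return status == "O"
    return True


def load_gene_info(
    path: str, species_taxids: Sequence[int]
) -> dict[int, list[GeneInfoRecord]]:
    """Load a gene_info table restricted to the requested taxa.

    Entries whose ``type_of_gene`` is ``unknown`` are removed entirely.
    Records without an official symbol (LOC-style provisional names, or an
    explicit non-official nomenclature status) stay in the per-species totals
    but are excluded from symbol matching via ``is_official=False``. The
    symbol reported is the nomenclature-authority symbol when present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationParseError(f"{path}: missing gene_info columns: {missing}")
    has_status = _NOMENCLATURE_STATUS in df.columns
    wanted = set(int(t) for t in species_taxids)
    out: dict[int, list[GeneInfoRecord]] = {t: [] for t in sorted(wanted)}
    for _, row in df.iterrows():
        tax = int(row["tax_id"])
        if tax not in wanted:
            continue
        type_of_gene = str(row["type_of_gene"])
        if type_of_gene.lower() == "unknown":
            continue
        symbol = str(row["Symbol"])
        if has_status and _NOMENCLATURE_SYMBOL in df.columns:
            auth = str(row.get(_NOMENCLATURE_SYMBOL, "-"))
            if auth != "-" and str(row.get(_NOMENCLATURE_STATUS, "-")) == "O":
                symbol = auth
        out[tax].append(
            GeneInfoRecord(
                tax_id=tax,
                entrez_id=str(row["GeneID"]),
                symbol=symbol,
                is_official=_record_is_official(row, has_status),
                type_of_gene=type_of_gene,
                description=str(row.get("description", "")),
            )
        )
    for recs in out.values():
        recs.sort(key=lambda r: (r.symbol.upper(), r.entrez_id))
    return out


def filter_qtl(records: Iterable[GeneInfoRecord]) -> list[GeneInfoRecord]:
    """Drop QTL records, whose symbols can collide with real gene symbols.

    A record is a QTL when its type of gene or its description contains the
    token QTL at a word boundary.
    """
    return [
        r
        for r in records
        if not (mentions_qtl(r.type_of_gene) or mentions_qtl(r.description))
    ]


def _official_symbol_map(records: Iterable[GeneInfoRecord]) -> dict[str, list[str]]:
    """Collapse records on upper-cased official symbol → sorted Entrez IDs."""
    by_symbol: dict[str, list[str]] = {}
    for r in records:
        if r.is_official:
            by_symbol.setdefault(r.symbol.upper(), []).append(r.entrez_id)
    return {s: sorted(ids) for s, ids in by_symbol.items()}


def match_symbols(
    records_a: Iterable[GeneInfoRecord], records_b: Iterable[GeneInfoRecord]
) -> list[SymbolPair]:
    """Pair Entrez IDs across two species on identical official symbols.

    Each species is collapsed on symbol first; when a symbol maps to several
    IDs on either side the full cross-product is emitted, flagged
    one-to-many so the merger's filter can deal with it.
    """
    map_a = _official_symbol_map(records_a)
    map_b = _official_symbol_map(records_b)
    pairs: list[SymbolPair] = []
    for symbol in sorted(set(map_a) & set(map_b)):
        ids_a, ids_b = map_a[symbol], map_b[symbol]
        flag = len(ids_a) > 1 or len(ids_b) > 1
        for a in ids_a:
            for b in ids_b:
                pairs.append(SymbolPair(entrez_a=a, entrez_b=b, symbol=symbol, one_to_many=flag))
    return pairs


def match_matrix(records_by_taxid: dict[int, list[GeneInfoRecord]]) -> SymbolMatchMatrix:
    """Pairwise percent of official symbols shared between species."""
    taxids = sorted(records_by_taxid)
    sets = {t: set(_official_symbol_map(records_by_taxid[t])) for t in taxids}
    mat = pd.DataFrame(index=taxids, columns=taxids, dtype=float)
    for s in taxids:
        for t in taxids:
            mat.loc[s, t] = 100.0 * len(sets[s] & sets[t]) / len(sets[s]) if sets[s] else 0.0
    return SymbolMatchMatrix(
        taxids=taxids,
        n_genes={t: len(records_by_taxid[t]) for t in taxids},
        n_official={t: len(sets[t]) for t in taxids},
        matrix=mat,
    )
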
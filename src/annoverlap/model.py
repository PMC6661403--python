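"""Core domain types shared across the package.

Coordinates are 1-based and inclusive on both ends, exactly as GFF3/GTF store
them on disk; every width computation therefore uses ``end - start + 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

NCBI = "NCBI"
ENSEMBL = "ENSEMBL"

#: Sequence-name prefixes that mark alternative-locus / unplaced scaffolds in
#: NCBI assemblies. Genes duplicated between the primary assembly and such
#: scaffolds are reduced to the primary copy during harmonization.
ALT_LOCI_PREFIXES = ("NT_", "NW_")


class AnnotationError(Exception):
    """Base class for annotation input problems."""


class AnnotationParseError(AnnotationError):
    """A file could not be parsed; the message names the offending line."""


class AssemblyMismatchError(AnnotationError):
    """The two annotation sets do not describe the same genome assembly."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a named sequence.

    ``start``/``end`` are 1-based inclusive; ``strand`` is ``+``, ``-`` or
    ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """One annotated gene: its span plus flattened exon and CDS intervals.

    ``gene_id`` is the Entrez Gene ID for NCBI-sourced genes and the Ensembl
    stable ID for Ensembl-sourced genes. Either feature list may be empty —
    both annotation providers ship genes without annotated exons or CDS.
    """

    gene_id: str
    source: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)
    symbol: Optional[str] = None
    biotype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in (NCBI, ENSEMBL):
            raise ValueError(f"source must be NCBI or ENSEMBL, got {self.source!r}")
        for iv in list(self.exons) + list(self.cds):
            if iv.chrom != self.span.chrom:
                raise ValueError(
                    f"feature on {iv.chrom} does not lie on gene chrom {self.span.chrom}"
                )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    def on_alt_locus(self) -> bool:
        return self.span.chrom.startswith(ALT_LOCI_PREFIXES)


@dataclass
class AnnotationSet:
    """All genes parsed from one annotation source for one assembly.

    Genes are kept as a list because, before harmonization, the same gene ID
    may legitimately occur more than once (primary chromosome plus an
    alternative-locus scaffold). After :func:`annoverlap.annotation_io.harmonize`
    the gene IDs are unique.
    """

    source: str
    assembly: Optional[str]
    genes: list[GeneModel] = field(default_factory=list)
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (ident, reason)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def duplicate_ids(self) -> set[str]:
        seen: set[str] = set()
        dups: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                dups.add(g.gene_id)
            seen.add(g.gene_id)
        return dups

    def by_id(self) -> dict[str, GeneModel]:
        """Genes keyed by ID; raises if the set still contains duplicates."""
        dups = self.duplicate_ids()
        if dups:
            raise AnnotationError(
                f"gene IDs not unique (run harmonize first): {sorted(dups)[:5]}"
            )
        return {g.gene_id: g for g in self.genes}


_QTL_TOKEN = re.compile(r"\bQTL\b", re.IGNORECASE)
_LOC_SYMBOL = re.compile(r"^LOC\d+$")


def looks_like_loc_symbol(symbol: str) -> bool:
    """True for provisional locus-number symbols such as ``LOC100152218``."""
    return bool(_LOC_SYMBOL.match(symbol))


def mentions_qtl(text: str) -> bool:
    """Word-boundary match for the token QTL (any case)."""
    return bool(_QTL_TOKEN.search(text or ""))


def envelope(intervals: Iterable[GenomicInterval]) -> GenomicInterval:
    """Smallest interval covering all inputs (they must share a chromosome)."""
    ivs = list(intervals)
    if not ivs:
        raise ValueError("envelope of no intervals")
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) != 1:
        raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
    strands = {iv.strand for iv in ivs}
    strand = strands.pop() if len(strands) == 1 else "."
    return GenomicInterval(
        chrom=ivs[0].chrom,
        start=min(iv.start for iv in ivs),
        end=max(iv.end for iv in ivs),
        strand=strand,
    )
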
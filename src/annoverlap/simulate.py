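"""Deterministic synthetic fixtures with machine-readable truth tables.

The generator fabricates the four input kinds the package consumes — paired
GFF3/GTF annotation with planted NCBI↔Ensembl correspondences, gene_info
tables, Compara-style dump tables and BLAST tabular output — each together
with a truth table stating what the corresponding pipeline must recover.

The annotation scenarios cover the hard cases annotation reconciliation
actually faces: partially (protruding) overlapping genes above and below the
pre-filter cut-off, genes contained in larger partners, one gene annotated
as two in the other source, tandem clusters sharing exons
(protocadherin-style), redundant gene IDs on alternative-locus scaffolds,
genes without exon/CDS annotation, and plain non-overlapping decoys.

Expected decisions in the truth table are computed by a naive base-set
oracle (explicit sets of covered base positions) inside this module, kept
deliberately independent of the interval arithmetic in
:mod:`annoverlap.overlap` that the truth is used to test. Geometry violating
a case-class constraint makes generation fail rather than emit a wrong
truth.

Everything is driven by a seed; the same seed yields byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_io import write_gff3, write_gtf
from .model import ENSEMBL, NCBI, AnnotationSet, GeneModel, GenomicInterval


class GenerationError(Exception):
    """Raised when a scenario config is infeasible or geometry checks fail."""


# expected-decision vocabulary of truth tables (matches the pipeline's labels)
T_DIRECT = "direct_positive"
T_RESCUED = "rescued_positive"
T_DISMISSED = "dismissed_prefilter"
T_REJECTED = "rejected"
T_DROPPED = "dropped_duplicate"
T_NONE = "none"

CASE_CLASSES = [
    "clean_pair",
    "protruding_above",
    "protruding_below",
    "contained",
    "split_gene",
    "shared_exon_cluster",
    "alt_loci_duplicate",
    "exonless_gene",
    "cds_only_gene",
    "decoy_nonoverlapping",
]

TRUTH_COLUMNS = [
    "case_id",
    "case_class",
    "ncbi_id",
    "ensembl_id",
    "expected_decision",
    "expected_pair",
]


@dataclass
class ScenarioConfig:
    """Counts per planted case class plus layout parameters.

    The defaults define the package's standard study scenario: 215 NCBI
    genes across all ten case classes on three chromosomes.
    """

    seed: int = 17
    n_chromosomes: int = 3
    chrom_length: int = 30_000_000
    assembly: str = "SynAsm1.0"
    clean_pair: int = 60
    protruding_above: int = 25
    protruding_below: int = 20
    contained: int = 25
    split_gene: int = 10
    shared_exon_cluster: int = 5
    alt_loci_duplicate: int = 10
    exonless_gene: int = 15
    cds_only_gene: int = 15
    decoy_nonoverlapping: int = 20
    gap_min: int = 2_000
    gap_max: int = 8_000
    # thresholds the planted geometry is built against (the pipeline defaults)
    min_protruding_frac: float = 0.25
    direct_accept_frac: float = 0.50
    feature_accept_frac: float = 0.50

    def case_counts(self) -> dict[str, int]:
        counts = {c: getattr(self, c) for c in CASE_CLASSES}
        if any(v < 0 for v in counts.values()):
            raise GenerationError("case counts must be >= 0")
        return counts


# ----------------------------------------------------------------------------
# naive base-set oracle


def _bases(iv: GenomicInterval) -> frozenset[int]:
    return frozenset(range(iv.start, iv.end + 1))


def _oracle_gene_candidate(a: GeneModel, b: GeneModel) -> Optional[dict]:
    if a.chrom != b.chrom:
        return None
    ab, bb = _bases(a.span), _bases(b.span)
    inter = ab & bb
    if not inter:
        return None
    if ab == bb:
        topo = "identical"
    elif ab <= bb or bb <= ab:
        topo = "contained"
    else:
        topo = "protruding"
    return {"frac": len(inter) / min(len(ab), len(bb)), "topology": topo}


def _oracle_feature_mean(
    feats_a: list[GenomicInterval], feats_b: list[GenomicInterval]
) -> Optional[float]:
    if not feats_a or not feats_b:
        return None
    ratios = []
    for fa in feats_a:
        for fb in feats_b:
            sa, sb = _bases(fa), _bases(fb)
            inner = sa & sb
            if inner:
                union_env = sa | sb
                outer = max(union_env) - min(union_env) + 1
                ratios.append(len(inner) / outer)
    return sum(ratios) / len(ratios) if ratios else None


def _oracle_decide_case(
    ncbi_genes: list[GeneModel], ens_genes: list[GeneModel], cfg: ScenarioConfig
) -> dict[tuple[str, str], str]:
    """Full naive pipeline over the genes of one case; returns decisions."""
    decisions: dict[tuple[str, str], str] = {}
    scored: dict[tuple[str, str], tuple[float, float]] = {}
    for ng in ncbi_genes:
        for eg in ens_genes:
            cand = _oracle_gene_candidate(ng, eg)
            if cand is None:
                continue
            key = (ng.gene_id, eg.gene_id)
            if cand["topology"] == "protruding" and cand["frac"] < cfg.min_protruding_frac:
                decisions[key] = T_DISMISSED
                continue
            em = _oracle_feature_mean(ng.exons, eg.exons)
            cm = _oracle_feature_mean(ng.cds, eg.cds)
            feat_best = max([v for v in (em, cm) if v is not None], default=-1.0)
            if cand["frac"] > cfg.direct_accept_frac:
                decisions[key] = T_DIRECT
            elif feat_best > cfg.feature_accept_frac:
                decisions[key] = T_RESCUED
            else:
                decisions[key] = T_REJECTED
                continue
            scored[key] = (cand["frac"], feat_best)
    # naive best-hit duplicate reduction to a mutually-best one-to-one set
    alive = dict(scored)
    while True:
        best_n: dict[str, tuple] = {}
        best_e: dict[str, tuple] = {}
        for (n, e), sc in alive.items():
            rank_n = (sc, tuple(-ord(c) for c in e))
            if n not in best_n or rank_n > best_n[n][0]:
                best_n[n] = (rank_n, e)
            rank_e = (sc, tuple(-ord(c) for c in n))
            if e not in best_e or rank_e > best_e[e][0]:
                best_e[e] = (rank_e, n)
        survivors = {
            k: sc
            for k, sc in alive.items()
            if best_n[k[0]][1] == k[1] and best_e[k[1]][1] == k[0]
        }
        if len(survivors) == len(alive):
            break
        alive = survivors
    for key in scored:
        if key not in alive:
            decisions[key] = T_DROPPED
    return decisions


# ----------------------------------------------------------------------------
# geometry builders (one per case class)


def _iv(chrom: str, start: int, end: int, strand: str = "+") -> GenomicInterval:
    return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)


def _mk_gene(gene_id, source, chrom, start, end, exons=(), cds=(), symbol=None):
    return GeneModel(
        gene_id=gene_id,
        source=source,
        span=_iv(chrom, start, end),
        exons=[_iv(chrom, a, b) for a, b in exons],
        cds=[_iv(chrom, a, b) for a, b in cds],
        symbol=symbol,
        biotype="protein_coding",
    )


class _ScenarioBuilder:
    def __init__(self, cfg: ScenarioConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.chroms = [str(i + 1) for i in range(cfg.n_chromosomes)]
        self.cursor = {c: 1_000 for c in self.chroms}
        self.ncbi: list[GeneModel] = []
        self.ens: list[GeneModel] = []
        self.truth_rows: list[dict] = []
        self._serial = 0
        self._case_serial = 0

    def next_entrez(self) -> str:
        self._serial += 1
        return str(100_000 + self._serial)

    def next_ensembl(self) -> str:
        return f"ENSTST{100_000 + self._serial:011d}"

    def place(self, chrom: str, extent: int) -> int:
        start = self.cursor[chrom]
        gap = int(self.rng.integers(self.cfg.gap_min, self.cfg.gap_max + 1))
        self.cursor[chrom] = start + extent + gap
        if self.cursor[chrom] > self.cfg.chrom_length:
            raise GenerationError(
                f"chromosome {chrom} overflows ({self.cursor[chrom]} > "
                f"{self.cfg.chrom_length}); reduce case counts or lengthen chroms"
            )
        return start

    def record(self, case_class, case_ncbi, case_ens, expectations):
        """Validate one case against the oracle, then append truth rows.

        ``expectations``: list of (ncbi_id, ensembl_id, decision, is_pair).
        """
        self._case_serial += 1
        case_id = f"case{self._case_serial:05d}"
        oracle = _oracle_decide_case(case_ncbi, case_ens, self.cfg)
        for (nid, eid, decision, is_pair) in expectations:
            if eid and nid:
                got = oracle.get((nid, eid), T_NONE)
                if got != decision:
                    raise GenerationError(
                        f"{case_class} {case_id}: oracle decided {got!r} for "
                        f"({nid}, {eid}), geometry intended {decision!r}"
                    )
            self.truth_rows.append(
                {
                    "case_id": case_id,
                    "case_class": case_class,
                    "ncbi_id": nid,
                    "ensembl_id": eid,
                    "expected_decision": decision,
                    "expected_pair": int(is_pair),
                }
            )
        self.ncbi.extend(case_ncbi)
        self.ens.extend(case_ens)

    # -- case classes ---------------------------------------------------------

    def add_clean_pair(self, chrom: str) -> None:
        length = int(self.rng.integers(1_000, 3_001))
        s = self.place(chrom, length)
        e = s + length - 1
        n_ex = int(self.rng.integers(2, 5))
        bounds = np.sort(self.rng.choice(np.arange(s + 10, e - 10), size=2 * n_ex, replace=False))
        exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex)]
        cds = exons[1:]
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, s, e, exons, cds, symbol=f"G{nid}")
        eg = _mk_gene(eid, ENSEMBL, chrom, s, e, exons, cds, symbol=f"G{nid}")
        self.record("clean_pair", [ng], [eg], [(nid, eid, T_DIRECT, True)])

    def add_protruding_above(self, chrom: str) -> None:
        # gene fraction in (0.25, 0.5]: passes the pre-filter, not direct;
        # one identical exon inside the shared region rescues the pair.
        length = 2_000
        ov = int(self.rng.integers(540, 901))  # frac 0.27..0.45
        s = self.place(chrom, 2 * length - ov)
        n_start, n_end = s, s + length - 1
        e_start, e_end = n_end - ov + 1, n_end - ov + length
        shared = (e_start + 10, e_start + 110)
        n_extra = (n_start + 50, n_start + 150)
        e_extra = (e_end - 150, e_end - 50)
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, n_start, n_end, [n_extra, shared], [shared])
        eg = _mk_gene(eid, ENSEMBL, chrom, e_start, e_end, [shared, e_extra], [shared])
        self.record("protruding_above", [ng], [eg], [(nid, eid, T_RESCUED, True)])

    def add_protruding_below(self, chrom: str) -> None:
        length = 2_000
        ov = int(self.rng.integers(50, 451))  # frac 0.025..0.2255 < 0.25
        s = self.place(chrom, 2 * length - ov)
        n_start, n_end = s, s + length - 1
        e_start, e_end = n_end - ov + 1, n_end - ov + length
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, n_start, n_end, [(n_start + 100, n_start + 300)])
        eg = _mk_gene(eid, ENSEMBL, chrom, e_start, e_end, [(e_end - 300, e_end - 100)])
        self.record("protruding_below", [ng], [eg], [(nid, eid, T_DISMISSED, False)])

    def add_contained(self, chrom: str) -> None:
        outer_len = int(self.rng.integers(2_500, 4_001))
        inner_len = int(self.rng.integers(800, 1_401))
        s = self.place(chrom, outer_len)
        offset = int(self.rng.integers(100, outer_len - inner_len - 100))
        nid, eid = self.next_entrez(), self.next_ensembl()
        e_start = s + offset
        exon = (e_start + 50, e_start + inner_len - 51)
        ng = _mk_gene(nid, NCBI, chrom, s, s + outer_len - 1, [exon], [exon])
        eg = _mk_gene(eid, ENSEMBL, chrom, e_start, e_start + inner_len - 1, [exon], [exon])
        self.record("contained", [ng], [eg], [(nid, eid, T_DIRECT, True)])

    def add_split_gene(self, chrom: str) -> None:
        # one NCBI gene covers two Ensembl genes (both contained, fraction 1);
        # the duplicate filter must keep the partner with the better exon
        # agreement and drop the other.
        s = self.place(chrom, 5_000)
        nid = self.next_entrez()
        eid1 = self.next_ensembl()
        self._serial += 1
        eid2 = f"ENSTST{100_000 + self._serial:011d}"
        exon1 = (s + 200, s + 700)
        exon2 = (s + 3_200, s + 3_700)
        exon2_shifted = (s + 3_400, s + 3_900)  # inner 301 / outer 701 vs exon2
        ng = _mk_gene(nid, NCBI, chrom, s, s + 4_999, [exon1, exon2], [exon1])
        eg1 = _mk_gene(eid1, ENSEMBL, chrom, s + 100, s + 1_899, [exon1], [exon1])
        eg2 = _mk_gene(eid2, ENSEMBL, chrom, s + 3_000, s + 4_799, [exon2_shifted])
        # both halves are contained (fraction 1.0); eid1 wins the tie on its
        # perfect exon agreement
        self.record(
            "split_gene",
            [ng],
            [eg1, eg2],
            [(nid, eid1, T_DIRECT, True), (nid, eid2, T_DROPPED, False)],
        )

    def add_shared_exon_cluster(self, chrom: str, size: int = 3) -> None:
        # Tandem genes overlapping their neighbours (fraction 0.4) and sharing
        # an exon with them, so every cross pair is rescued — only the
        # duplicate filter keeps the cluster one-to-one.
        step, length = 600, 1_000
        s = self.place(chrom, step * (size - 1) + length)
        starts = [s + i * step for i in range(size)]
        shared = [(st + 850, st + 930) for st in starts]  # shared[i]: genes i, i+1
        nids = [self.next_entrez() for _ in range(size)]
        eids = []
        for _ in range(size):
            self._serial += 1
            eids.append(f"ENSTST{100_000 + self._serial:011d}")
        ngenes, egenes = [], []
        for i, st in enumerate(starts):
            exons = [(st + 100, st + 200)]
            if i > 0:
                exons.append(shared[i - 1])
            if i < size - 1:
                exons.append(shared[i])
            exons.sort()
            ngenes.append(_mk_gene(nids[i], NCBI, chrom, st, st + length - 1, exons))
            egenes.append(_mk_gene(eids[i], ENSEMBL, chrom, st, st + length - 1, exons))
        expectations = [(nids[i], eids[i], T_DIRECT, True) for i in range(size)]
        for i in range(size - 1):
            expectations.append((nids[i], eids[i + 1], T_DROPPED, False))
            expectations.append((nids[i + 1], eids[i], T_DROPPED, False))
        self.record("shared_exon_cluster", ngenes, egenes, expectations)

    def add_alt_loci_duplicate(self, chrom: str) -> None:
        # the same Entrez ID on the primary chromosome and an NW_ scaffold;
        # harmonization keeps the primary copy, which then pairs normally.
        length = int(self.rng.integers(1_200, 2_501))
        s = self.place(chrom, length)
        exon = (s + 100, s + length - 101)
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, s, s + length - 1, [exon], [exon])
        scaffold = f"NW_{900_000 + self._serial}.1"
        ng_alt = _mk_gene(nid, NCBI, scaffold, 5_000, 5_000 + length - 1)
        eg = _mk_gene(eid, ENSEMBL, chrom, s, s + length - 1, [exon], [exon])
        # oracle sees the post-harmonization state: primary copy only
        self.record("alt_loci_duplicate", [ng], [eg], [(nid, eid, T_DIRECT, True)])
        self.ncbi.append(ng_alt)

    def add_exonless_gene(self, chrom: str) -> None:
        # fraction 0.3..0.45 (needs feature rescue) but the Ensembl gene has
        # no exons or CDS: the means are absent and the pair is rejected.
        length = 2_000
        ov = int(self.rng.integers(600, 901))
        s = self.place(chrom, 2 * length - ov)
        n_end = s + length - 1
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, s, n_end, [(s + 100, s + 400)], [(s + 150, s + 350)])
        eg = _mk_gene(eid, ENSEMBL, chrom, n_end - ov + 1, n_end - ov + length)
        self.record("exonless_gene", [ng], [eg], [(nid, eid, T_REJECTED, False)])

    def add_cds_only_gene(self, chrom: str) -> None:
        # exon sets never overlap between the partners, but an identical CDS
        # in the shared region rescues the pair.
        length = 2_000
        ov = 800
        s = self.place(chrom, 2 * length - ov)
        n_start, n_end = s, s + length - 1
        e_start, e_end = n_end - ov + 1, n_end - ov + length
        cds = (e_start + 100, e_start + 300)
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, n_start, n_end, [(n_start + 50, n_start + 250)], [cds])
        eg = _mk_gene(eid, ENSEMBL, chrom, e_start, e_end, [(e_end - 250, e_end - 50)], [cds])
        self.record("cds_only_gene", [ng], [eg], [(nid, eid, T_RESCUED, True)])

    def add_decoy_nonoverlapping(self, chrom: str) -> None:
        length = int(self.rng.integers(800, 1_501))
        s1 = self.place(chrom, length)
        s2 = self.place(chrom, length)
        nid, eid = self.next_entrez(), self.next_ensembl()
        ng = _mk_gene(nid, NCBI, chrom, s1, s1 + length - 1, [(s1 + 50, s1 + 150)])
        eg = _mk_gene(eid, ENSEMBL, chrom, s2, s2 + length - 1, [(s2 + 50, s2 + 150)])
        self.record("decoy_nonoverlapping", [ng], [eg], [(nid, eid, T_NONE, False)])

    def build(self) -> tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
        counts = self.cfg.case_counts()
        i = 0
        for case_class in CASE_CLASSES:
            adder = getattr(self, f"add_{case_class}")
            for _ in range(counts[case_class]):
                adder(self.chroms[i % len(self.chroms)])
                i += 1
        ncbi = AnnotationSet(source=NCBI, assembly=self.cfg.assembly, genes=self.ncbi)
        ens = AnnotationSet(source=ENSEMBL, assembly=self.cfg.assembly, genes=self.ens)
        ncbi.genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
        ens.genes.sort(key=lambda g: (g.chrom, g.span.start, g.gene_id))
        truth = pd.DataFrame(self.truth_rows, columns=TRUTH_COLUMNS)
        return ncbi, ens, truth


def build_annotation_pair(
    config: ScenarioConfig,
) -> tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
    """In-memory variant of :func:`generate_annotation_pair`."""
    return _ScenarioBuilder(config).build()


def generate_annotation_pair(
    config: ScenarioConfig, out_dir: str
) -> tuple[str, str, pd.DataFrame]:
    """Write the planted GFF3/GTF pair plus ``truth_annotation.tsv``.

    Returns (gff3 path, gtf path, truth table). The truth table lists, per
    planted case, the expected pipeline decision for each considered ID pair
    and whether it belongs in the final lookup table.
    """
    ncbi, ens, truth = build_annotation_pair(config)
    os.makedirs(out_dir, exist_ok=True)
    gff3 = os.path.join(out_dir, "ncbi.gff3")
    gtf = os.path.join(out_dir, "ensembl.gtf")
    write_gff3(ncbi, gff3)
    write_gtf(ens, gtf)
    truth.to_csv(os.path.join(out_dir, "truth_annotation.tsv"), sep="\t", index=False)
    return gff3, gtf, truth


# ----------------------------------------------------------------------------
# gene_info generator


@dataclass
class GeneInfoConfig:
    seed: int = 17
    taxids: tuple[int, int] = (9606, 9823)
    n_official: int = 10          # official symbols per species
    n_shared: int = 8             # of which shared between the two species
    n_loc: int = 3                # provisional LOC-symbol records per species
    n_qtl: int = 1                # QTL records colliding with real symbols
    n_unknown: int = 1            # records with type_of_gene "unknown"


GENE_INFO_COLUMNS = [
    "#tax_id",
    "GeneID",
    "Symbol",
    "description",
    "type_of_gene",
    "Symbol_from_nomenclature_authority",
    "Nomenclature_status",
]


def generate_gene_info(config: GeneInfoConfig, out_path: str) -> dict:
    """Write a two-species gene_info fixture; returns the truth dict.

    Truth keys: ``expected_pct`` (percent of either species' official
    symbols found in the other), ``expected_pairs`` (symbol pairs after
    filtering), ``qtl_ids`` and ``unknown_ids`` (Entrez IDs that the filters
    must remove).
    """
    if config.n_shared > config.n_official:
        raise GenerationError("n_shared cannot exceed n_official")
    rng = np.random.default_rng(config.seed)
    tax_a, tax_b = config.taxids
    n_unique = config.n_official - config.n_shared
    shared = [f"GN{i:04d}" for i in range(config.n_shared)]
    unique_a = [f"GA{i:04d}" for i in range(n_unique)]
    unique_b = [f"GB{i:04d}" for i in range(n_unique)]
    rows: list[dict] = []
    truth = {
        "expected_pct": (100.0 * config.n_shared / config.n_official
                         if config.n_official else 0.0),
        "expected_pairs": config.n_shared,
        "qtl_ids": [],
        "unknown_ids": [],
        "taxids": list(config.taxids),
    }
    serial = {tax_a: 1000, tax_b: 2000}

    def add(tax, symbol, type_of_gene="protein-coding", description="", status="O"):
        serial[tax] += 1
        gid = str(serial[tax])
        rows.append(
            {
                "#tax_id": tax,
                "GeneID": gid,
                "Symbol": symbol,
                "description": description or f"gene {symbol}",
                "type_of_gene": type_of_gene,
                "Symbol_from_nomenclature_authority": symbol if status == "O" else "-",
                "Nomenclature_status": status,
            }
        )
        return gid

    for sym in shared:
        # cross-species case convention: lower-case tail in species B
        add(tax_a, sym)
        add(tax_b, sym if rng.random() < 0.5 else sym.capitalize())
    for sym in unique_a:
        add(tax_a, sym)
    for sym in unique_b:
        add(tax_b, sym)
    for tax in (tax_a, tax_b):
        for _ in range(config.n_loc):
            serial[tax] += 1
            add(tax, f"LOC{serial[tax]}00", status="-")
    # QTL records in species B whose symbol collides with a species-A-only
    # official symbol: without the QTL filter it would create a false match.
    for i in range(config.n_qtl):
        collide = unique_a[i % len(unique_a)] if unique_a else shared[0]
        gid = add(tax_b, collide, type_of_gene="other",
                  description=f"QTL for trait {i}", status="-")
        truth["qtl_ids"].append(gid)
    for i in range(config.n_unknown):
        tax = (tax_a, tax_b)[i % 2]
        gid = add(tax, f"UNK{i:03d}", type_of_gene="unknown", status="-")
        truth["unknown_ids"].append(gid)
    df = pd.DataFrame(rows, columns=GENE_INFO_COLUMNS)
    df.to_csv(out_path, sep="\t", index=False)
    return truth


# ----------------------------------------------------------------------------
# Compara dump generator


@dataclass
class ComparaConfig:
    seed: int = 17
    species: tuple[str, str] = ("homo_sapiens", "sus_scrofa")
    other_species: str = "mus_musculus"
    n_homologies: int = 6          # within the configured species pair
    n_other: int = 1               # homologies involving the other species
    n_dangling: int = 1            # homologies with a missing gene_member row
    ortholog_types: tuple[str, ...] = (
        "ortholog_one2one",
        "ortholog_one2many",
        "within_species_paralog",
    )


def generate_compara_tables(config: ComparaConfig, out_dir: str) -> dict:
    """Write the four Compara-style dump tables; returns the truth dict.

    Truth keys: ``retained`` (homology_id → (stable_a, stable_b, type) for
    homologies within the species pair), ``skipped`` (expected skip count
    from dangling members), ``stable_ids`` per species.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    sp_a, sp_b = config.species
    genome_db = pd.DataFrame(
        [
            {"genome_db_id": "1", "taxon_id": "9606", "name": sp_a, "assembly": "AsmA"},
            {"genome_db_id": "2", "taxon_id": "9823", "name": sp_b, "assembly": "AsmB"},
            {"genome_db_id": "3", "taxon_id": "10090", "name": config.other_species, "assembly": "AsmC"},
        ]
    )
    gdb_id = {sp_a: "1", sp_b: "2", config.other_species: "3"}
    gene_member_rows, homology_rows, hm_rows = [], [], []
    truth = {"retained": {}, "skipped": config.n_dangling, "stable_ids": {sp_a: [], sp_b: []}}
    gm_serial = [0]

    def add_member(species, prefix):
        gm_serial[0] += 1
        stable = f"{prefix}{gm_serial[0]:09d}"
        gene_member_rows.append(
            {
                "gene_member_id": str(gm_serial[0]),
                "stable_id": stable,
                "genome_db_id": gdb_id[species],
                "display_label": f"SYM{gm_serial[0]}",
                "dnafrag_name": str(int(rng.integers(1, 5))),
                "description": f"synthetic gene {stable}",
                "biotype": "protein_coding",
            }
        )
        if species in truth["stable_ids"]:
            truth["stable_ids"][species].append(stable)
        return str(gm_serial[0]), stable

    hid = 0
    for _ in range(config.n_homologies):
        hid += 1
        otype = config.ortholog_types[int(rng.integers(0, len(config.ortholog_types)))]
        ma, sa = add_member(sp_a, "ENSG")
        mb, sb = add_member(sp_b, "ENSSSCG")
        homology_rows.append({"homology_id": str(hid), "description": otype})
        for gm in (ma, mb):
            hm_rows.append(
                {
                    "homology_id": str(hid),
                    "gene_member_id": gm,
                    "perc_cov": f"{rng.uniform(60, 100):.1f}",
                    "perc_id": f"{rng.uniform(50, 100):.1f}",
                    "perc_pos": f"{rng.uniform(50, 100):.1f}",
                }
            )
        truth["retained"][str(hid)] = (sa, sb, otype)
    for _ in range(config.n_other):
        hid += 1
        ma, _ = add_member(sp_a, "ENSG")
        mo, _ = add_member(config.other_species, "ENSMUSG")
        homology_rows.append({"homology_id": str(hid), "description": "ortholog_one2one"})
        for gm in (ma, mo):
            hm_rows.append(
                {"homology_id": str(hid), "gene_member_id": gm,
                 "perc_cov": "90.0", "perc_id": "85.0", "perc_pos": "88.0"}
            )
    for _ in range(config.n_dangling):
        hid += 1
        ma, _ = add_member(sp_a, "ENSG")
        homology_rows.append({"homology_id": str(hid), "description": "ortholog_one2one"})
        hm_rows.append(
            {"homology_id": str(hid), "gene_member_id": ma,
             "perc_cov": "90.0", "perc_id": "85.0", "perc_pos": "88.0"}
        )
        hm_rows.append(
            {"homology_id": str(hid), "gene_member_id": "999999",  # dangling
             "perc_cov": "90.0", "perc_id": "85.0", "perc_pos": "88.0"}
        )
    paths = {}
    for name, frame in (
        ("genome_db", genome_db),
        ("gene_member", pd.DataFrame(gene_member_rows)),
        ("homology", pd.DataFrame(homology_rows)),
        ("homology_member", pd.DataFrame(hm_rows)),
    ):
        p = os.path.join(out_dir, f"{name}.tsv")
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    truth["paths"] = paths
    return truth


# ----------------------------------------------------------------------------
# BLAST tabular generator


@dataclass
class BlastConfig:
    seed: int = 17
    n_genes: int = 10              # query genes with a true subject partner
    tx_per_gene: int = 2
    n_subthreshold: int = 2        # hits planted below the filter thresholds
    n_ties: int = 1                # query transcripts with a bit-score tie
    min_bitscore: float = 50.0
    min_qcov: float = 70.0


def generate_blast_tab(config: BlastConfig, out_dir: str) -> dict:
    """Write BLAST outfmt-6+qcovs output plus tx2gene maps; returns truth.

    Truth keys: ``expected_pairs`` (gene_query, gene_subject) → support
    count, ``tie_winners`` (query transcript → subject transcript expected
    from the bit-score tie-break), ``paths``.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)
    rows: list[list] = []
    tx2gene_q: dict[str, str] = {}
    tx2gene_s: dict[str, str] = {}
    truth = {"expected_pairs": {}, "tie_winners": {}}

    def hit(q, s, bit, pident, qcov, evalue="1e-50"):
        length = int(rng.integers(200, 2_000))
        rows.append(
            [q, s, f"{pident:.2f}", str(length), "5", "1", "1", str(length),
             "1", str(length), evalue, f"{bit:.1f}", f"{qcov:.0f}"]
        )

    for i in range(config.n_genes):
        gq, gs = f"QGENE{i:03d}", f"SGENE{i:03d}"
        support = 0
        for t in range(config.tx_per_gene):
            q = f"QTX{i:03d}.{t}"
            s = f"STX{i:03d}.{t}"
            tx2gene_q[q] = gq
            tx2gene_s[s] = gs
            bit = float(rng.uniform(200, 900))
            hit(q, s, bit, rng.uniform(85, 99.5), rng.uniform(80, 100))
            # a weaker secondary hit to the next gene's transcript
            alt = f"STX{(i + 1) % config.n_genes:03d}.0"
            tx2gene_s.setdefault(alt, f"SGENE{(i + 1) % config.n_genes:03d}")
            hit(q, alt, bit - float(rng.uniform(20, 100)), rng.uniform(70, 90), rng.uniform(75, 95))
            support += 1
        truth["expected_pairs"][(gq, gs)] = support
    for i in range(config.n_subthreshold):
        q = f"QTXLOW{i:02d}.0"
        s = f"STXLOW{i:02d}.0"
        tx2gene_q[q] = f"QGENELOW{i:02d}"
        tx2gene_s[s] = f"SGENELOW{i:02d}"
        if i % 2 == 0:
            hit(q, s, config.min_bitscore - 10, 80.0, 90.0)      # bit too low
        else:
            hit(q, s, config.min_bitscore + 100, 80.0, config.min_qcov - 10)  # qcov too low
    for i in range(config.n_ties):
        q = f"QTXTIE{i:02d}.0"
        s1, s2 = f"STXTIE{i:02d}.a", f"STXTIE{i:02d}.b"
        gq = f"QGENETIE{i:02d}"
        tx2gene_q[q] = gq
        tx2gene_s[s1] = f"SGENETIE{i:02d}A"
        tx2gene_s[s2] = f"SGENETIE{i:02d}B"
        # equal bit score; s2 wins on higher percent identity
        hit(q, s1, 400.0, 95.0, 90.0)
        hit(q, s2, 400.0, 99.0, 90.0)
        truth["tie_winners"][q] = s2
        truth["expected_pairs"][(gq, tx2gene_s[s2])] = 1
    order = rng.permutation(len(rows))
    hits_path = os.path.join(out_dir, "blast_hits.tsv")
    with open(hits_path, "w") as fh:
        for idx in order:
            fh.write("\t".join(rows[idx]) + "\n")
    q_path = os.path.join(out_dir, "tx2gene_query.tsv")
    s_path = os.path.join(out_dir, "tx2gene_subject.tsv")
    for path, mapping in ((q_path, tx2gene_q), (s_path, tx2gene_s)):
        with open(path, "w") as fh:
            fh.write("transcript\tgene\n")
            for tx in sorted(mapping):
                fh.write(f"{tx}\t{mapping[tx]}\n")
    truth["paths"] = {"hits": hits_path, "tx2gene_query": q_path, "tx2gene_subject": s_path}
    return truth
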
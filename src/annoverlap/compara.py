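"""Ensembl Compara homology dumps → the merged ``all_ortholog`` table.

Compara publishes homology calls as relational dump tables. This module
joins the four tables involved (``genome_db``, ``gene_member``, ``homology``,
``homology_member``), restricts them to a configured species set, and — via
the Entrez↔Ensembl lookup table produced by :mod:`annoverlap.overlap` —
emits one row per homology member with its Entrez ID attached.

The dump schema varies between Ensembl releases; the column subset consumed
here (documented per table below) is pinned to the fixture schema the
package ships, and real dumps need their headers reduced to it.

Expected columns:

* ``genome_db``: genome_db_id, taxon_id, name, assembly
* ``gene_member``: gene_member_id, stable_id, genome_db_id, display_label,
  dnafrag_name, description, biotype
* ``homology``: homology_id, description   (the ortholog/paralog class)
* ``homology_member``: homology_id, gene_member_id, perc_cov, perc_id,
  perc_pos
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import AnnotationParseError
from .overlap import IdPair

#: Fixed column order of the all_ortholog table.
ALL_ORTHOLOG_COLUMNS = [
    "species_name",
    "stable_id",
    "entrez_gene_id",
    "gene_symbol",
    "perc_cov",
    "perc_id",
    "perc_pos",
    "ortholog_description",
    "chromosome",
    "gene_description",
    "type_of_gene",
    "database_source",
]


@dataclass(frozen=True)
class ComparaMember:
    stable_id: str
    species: str
    perc_cov: float
    perc_id: float
    perc_pos: float
    symbol: str = ""
    chromosome: str = ""
    description: str = ""
    biotype: str = ""


@dataclass
class ComparaHomology:
    """One pairwise homology: exactly two members plus its class string."""

    homology_id: str
    ortholog_type: str
    members: tuple[ComparaMember, ComparaMember]


def _read(path: str, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AnnotationParseError(f"{path}: missing columns: {missing}")
    return df


def parse_compara(
    gene_member_path: str,
    homology_path: str,
    homology_member_path: str,
    genome_db_path: str,
    species: Sequence[str],
    ortholog_types: Optional[Sequence[str]] = None,
) -> tuple[list[ComparaHomology], int]:
    """Join the dump tables and keep homologies within the species set.

    A homology survives when it has exactly two resolvable members and both
    belong to configured species (Compara ``genome_db.name`` production
    names, e.g. ``homo_sapiens``). ``ortholog_types``, when given, is an
    allowlist on the homology class string; by default every class — all
    ortholog and paralog types — is kept. Members referencing a missing
    gene_member row make the homology unresolvable: it is skipped and
    counted. Returns (homologies, skipped count).
    """
    genome_db = _read(genome_db_path, ["genome_db_id", "name"])
    gene_member = _read(
        gene_member_path, ["gene_member_id", "stable_id", "genome_db_id"]
    )
    homology = _read(homology_path, ["homology_id", "description"])
    homology_member = _read(
        homology_member_path,
        ["homology_id", "gene_member_id", "perc_cov", "perc_id", "perc_pos"],
    )
    members = gene_member.merge(genome_db[["genome_db_id", "name"]], on="genome_db_id", how="left")
    members = members.set_index("gene_member_id")
    species_set = set(species)
    type_set = set(ortholog_types) if ortholog_types else None
    by_homology = homology_member.groupby("homology_id", sort=True)
    classes = homology.set_index("homology_id")["description"].to_dict()
    out: list[ComparaHomology] = []
    skipped = 0
    for hid, group in by_homology:
        if hid not in classes or len(group) != 2:
            skipped += 1
            continue
        otype = classes[hid]
        if type_set is not None and otype not in type_set:
            continue
        pair: list[ComparaMember] = []
        ok = True
        for _, row in group.sort_values("gene_member_id").iterrows():
            gm = row["gene_member_id"]
            if gm not in members.index:
                ok = False
                break
            m = members.loc[gm]
            pair.append(
                ComparaMember(
                    stable_id=str(m["stable_id"]),
                    species=str(m["name"]),
                    perc_cov=float(row["perc_cov"]),
                    perc_id=float(row["perc_id"]),
                    perc_pos=float(row["perc_pos"]),
                    symbol=str(m.get("display_label", "") or ""),
                    chromosome=str(m.get("dnafrag_name", "") or ""),
                    description=str(m.get("description", "") or ""),
                    biotype=str(m.get("biotype", "") or ""),
                )
            )
        if not ok:
            skipped += 1
            continue
        if not all(m.species in species_set for m in pair):
            continue
        out.append(ComparaHomology(homology_id=str(hid), ortholog_type=otype, members=(pair[0], pair[1])))
    return out, skipped


def lookup_to_dict(lookup: Iterable[IdPair]) -> dict[str, str]:
    """Ensembl stable ID → Entrez ID from the one-to-one lookup table."""
    return {p.ensembl_id: p.ncbi_id for p in lookup}


def build_all_ortholog(
    homologies: Iterable[ComparaHomology],
    lookup: Mapping[str, str],
) -> pd.DataFrame:
    """One row per homology member, in the fixed 12-column layout.

    The Entrez column is filled through the lookup table and left empty for
    Ensembl genes the position-based pairing could not assign.
    """
    rows = []
    for h in homologies:
        for m in h.members:
            rows.append(
                {
                    "species_name": m.species,
                    "stable_id": m.stable_id,
                    "entrez_gene_id": lookup.get(m.stable_id, ""),
                    "gene_symbol": m.symbol,
                    "perc_cov": m.perc_cov,
                    "perc_id": m.perc_id,
                    "perc_pos": m.perc_pos,
                    "ortholog_description": h.ortholog_type,
                    "chromosome": m.chromosome,
                    "gene_description": m.description,
                    "type_of_gene": m.biotype,
                    "database_source": "compara",
                }
            )
    df = pd.DataFrame(rows, columns=ALL_ORTHOLOG_COLUMNS)
    return df.sort_values(["species_name", "stable_id", "ortholog_description"]).reset_index(drop=True)


def homologies_to_entrez_pairs(
    homologies: Iterable[ComparaHomology], lookup: Mapping[str, str]
) -> list[tuple[str, str, str, str, str]]:
    """(species_a, entrez_a, species_b, entrez_b, type) per fully mapped homology.

    Homologies with an unmapped member cannot be expressed in Entrez IDs and
    are omitted; members are ordered by species name, then stable ID, so the
    pair orientation is deterministic.
    """
    pairs = []
    for h in homologies:
        ms = sorted(h.members, key=lambda m: (m.species, m.stable_id))
        ids = [lookup.get(m.stable_id) for m in ms]
        if all(ids):
            pairs.append((ms[0].species, ids[0], ms[1].species, ids[1], h.ortholog_type))
    return pairs
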
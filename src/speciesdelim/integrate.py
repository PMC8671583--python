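"""Integration of phenotypic and genomic group systems.

Each specimen carries (at most) a phenogroup and a genogroup; crossing the
two partitions gives a two-way contingency table whose occupied cells are
the integrated species hypotheses:

* **good species** — a cell whose row and column each hold exactly one
  occupied cell: one phenogroup and one genogroup co-identify the same
  specimens;
* **phenotypic cryptic species** — cells of a phenogroup (row) that spans
  several genogroups, each of those genogroups mapping back to that single
  phenogroup: genetically distinct lineages hidden under one phenotype;
* **genetic cryptic species** — the mirror image, one genogroup spanning
  several single-genogroup phenogroups;
* **complex** — both the row and the column are multiply occupied; the
  three-way typology does not cover this interlocking pattern, so it is
  labelled explicitly rather than forced into a type.

Specimens with only one kind of data ("unknown specimens") sit in the table
margins; they never populate cells.  Correspondence with the current
taxonomy is summarised as counts of *perfect matches*: a taxonomic species
and a delimited group whose specimen sets coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import check_assignment_series

__all__ = [
    "ContingencyTable",
    "SpeciesCell",
    "CorrespondenceReport",
    "build_contingency",
    "classify_cells",
    "perfect_matches",
    "correspondence_summary",
    "propagate_unknowns",
]


@dataclass
class ContingencyTable:
    """Phenogroup x genogroup specimen counts with unknown-specimen margins."""

    counts: pd.DataFrame  # index: phenogroups, columns: genogroups
    members: dict[tuple[str, str], list[str]]
    unknown_pheno_only: list[str]  # specimens with a phenogroup but no genogroup
    unknown_geno_only: list[str]

    @property
    def n_assigned(self) -> int:
        return int(self.counts.values.sum())

    @property
    def n_unknown(self) -> int:
        return len(self.unknown_pheno_only) + len(self.unknown_geno_only)


def build_contingency(
    pheno: Mapping[str, str] | pd.Series,
    geno: Mapping[str, str] | pd.Series,
    all_ids=None,
) -> ContingencyTable:
    """Cross-tabulate the two assignment systems.

    Specimens present in both systems populate the cells; specimens with
    only one assignment go to the corresponding unknown margin.  When
    ``all_ids`` is given, any id carrying neither assignment is an error.
    """
    pheno = check_assignment_series(pheno)
    geno = check_assignment_series(geno)
    if all_ids is not None:
        orphans = sorted(set(all_ids) - set(pheno.index) - set(geno.index))
        if orphans:
            raise ValueError(f"specimens with neither assignment: {orphans}")
    both = pheno.index.intersection(geno.index)
    only_p = [i for i in pheno.index if i not in geno.index]
    only_g = [i for i in geno.index if i not in pheno.index]
    prow = pheno.loc[both]
    grow = geno.loc[both]
    counts = pd.crosstab(prow, grow) if len(both) else pd.DataFrame()
    counts.index.name = "phenogroup"
    counts.columns.name = "genogroup"
    members: dict[tuple[str, str], list[str]] = {}
    for sid in both:
        members.setdefault((prow[sid], grow[sid]), []).append(sid)
    return ContingencyTable(
        counts=counts, members=members, unknown_pheno_only=only_p, unknown_geno_only=only_g
    )


@dataclass(frozen=True)
class SpeciesCell:
    """One occupied contingency cell: an integrated species hypothesis."""

    phenogroup: str
    genogroup: str
    count: int
    species_type: str  # good | phenotypic_cryptic | genetic_cryptic | complex


def classify_cells(table: ContingencyTable) -> list[SpeciesCell]:
    """Type every occupied cell from its row/column occupancy pattern."""
    counts = table.counts
    if counts.size == 0 or not (counts.values > 0).any():
        raise ValueError("contingency table has no occupied cells")
    occ = counts.values > 0
    row_occ = occ.sum(axis=1)
    col_occ = occ.sum(axis=0)
    cells = []
    for i, p in enumerate(counts.index):
        for j, g in enumerate(counts.columns):
            if not occ[i, j]:
                continue
            if row_occ[i] == 1 and col_occ[j] == 1:
                kind = "good"
            elif row_occ[i] > 1 and col_occ[j] == 1:
                kind = "phenotypic_cryptic"
            elif row_occ[i] == 1 and col_occ[j] > 1:
                kind = "genetic_cryptic"
            else:
                kind = "complex"
            cells.append(SpeciesCell(str(p), str(g), int(counts.iloc[i, j]), kind))
    return cells


def perfect_matches(a: Mapping[str, str] | pd.Series, b: Mapping[str, str] | pd.Series) -> int:
    """Count block-for-block coincidences between two partitions.

    Restricted to specimens present in both systems; a match is a pair of
    groups (one per system) whose specimen sets are identical.  Symmetric in
    its arguments; for identical partitions it returns the block count.
    """
    a = check_assignment_series(a)
    b = check_assignment_series(b)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("the two partitions share no specimens")
    a = a.loc[common]
    b = b.loc[common]
    blocks_a = {g: frozenset(idx) for g, idx in a.groupby(a).groups.items()}
    blocks_b = {frozenset(idx) for _, idx in b.groupby(b).groups.items()}
    return sum(1 for s in blocks_a.values() if s in blocks_b)


@dataclass
class CorrespondenceReport:
    """Taxonomy-vs-delimitation summary in the correspondence-table layout."""

    n_taxa: int
    n_phenogroups: int
    n_genogroups: int
    match_pheno: int
    match_geno: int
    match_joint: int
    n_specimens_joint: int

    def to_row(self) -> dict:
        return {
            "taxonomic_species": self.n_taxa,
            "phenogroups": self.n_phenogroups,
            "perfect_match_pheno": self.match_pheno,
            "genogroups": self.n_genogroups,
            "perfect_match_geno": self.match_geno,
            "perfect_match_joint": self.match_joint,
        }


def correspondence_summary(
    taxa: Mapping[str, str] | pd.Series,
    pheno: Mapping[str, str] | pd.Series,
    geno: Mapping[str, str] | pd.Series,
) -> CorrespondenceReport:
    """Perfect-match counts of taxonomy against phenogroups, genogroups and
    their joint (product) partition over dually-assigned specimens."""
    taxa = check_assignment_series(taxa)
    pheno = check_assignment_series(pheno)
    geno = check_assignment_series(geno)
    joint_ids = pheno.index.intersection(geno.index)
    joint = pd.Series(
        [f"{pheno[i]}|{geno[i]}" for i in joint_ids], index=joint_ids
    )
    return CorrespondenceReport(
        n_taxa=int(taxa.nunique()),
        n_phenogroups=int(pheno.nunique()),
        n_genogroups=int(geno.nunique()),
        match_pheno=perfect_matches(taxa, pheno),
        match_geno=perfect_matches(taxa, geno),
        match_joint=perfect_matches(taxa, joint),
        n_specimens_joint=int(len(joint_ids)),
    )


def pooled_good_species_percent(species_counts, joint_match_counts) -> float:
    """Pooled percentage of taxonomic species that are 'good':
    sum of joint perfect matches over the summed species counts, x100."""
    total_species = int(np.sum(species_counts))
    total_matches = int(np.sum(joint_match_counts))
    if total_species == 0:
        raise ValueError("no species to pool")
    return 100.0 * total_matches / total_species


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    r = 6371.0
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(h))


def propagate_unknowns(
    table: ContingencyTable,
    geography: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Provisional assignments for unknown specimens by geographic majority.

    For each unknown specimen, take the ``k`` great-circle-nearest
    dually-assigned specimens and adopt the majority missing-side label;
    ties leave the specimen unassigned with a flag.  Output is provisional
    and kept separate from the primary counts.  ``geography`` must index
    lat/lon (decimal degrees) by specimen id.
    """
    assigned_ids = [sid for ids in table.members.values() for sid in ids]
    lookup = {
        sid: cell for cell, ids in table.members.items() for sid in ids
    }
    rows = []
    for sid, side in [(s, "genogroup") for s in table.unknown_pheno_only] + [
        (s, "phenogroup") for s in table.unknown_geno_only
    ]:
        if not assigned_ids or sid not in geography.index:
            rows.append({"specimen_id": sid, "missing_side": side, "provisional": None, "tie": False})
            continue
        lat, lon = geography.loc[sid, ["lat", "lon"]]
        alats = geography.loc[assigned_ids, "lat"].to_numpy(dtype=float)
        alons = geography.loc[assigned_ids, "lon"].to_numpy(dtype=float)
        dists = _haversine_km(float(lat), float(lon), alats, alons)
        kk = min(k, len(assigned_ids))
        nearest = np.argsort(dists, kind="stable")[:kk]
        col = 1 if side == "genogroup" else 0
        votes = pd.Series([lookup[assigned_ids[i]][col] for i in nearest]).value_counts()
        top = votes[votes == votes.max()]
        if len(top) > 1:
            rows.append({"specimen_id": sid, "missing_side": side, "provisional": None, "tie": True})
        else:
            rows.append(
                {"specimen_id": sid, "missing_side": side, "provisional": top.index[0], "tie": False}
            )
    return pd.DataFrame(rows, columns=["specimen_id", "missing_side", "provisional", "tie"])
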
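"""Readers and writers for the pipeline's file formats.

Traits travel as CSV (specimen_id, clade, taxon, lat, lon, elevation_m,
trait_*), genotypes as VCF 4.2 (GT only) or as 012 matrices with -1 for
missing, species range boxes as CSV (taxon, trait, min, max), assignments
and distances as TSV.  All tabular outputs carry a one-line header.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import GenotypeMatrix, SpeciesBoxSet, TraitMatrix

__all__ = [
    "read_traits",
    "write_traits",
    "read_vcf",
    "write_vcf",
    "read_012",
    "write_012",
    "read_ranges",
    "write_ranges",
    "write_assignments",
    "read_assignments_tsv",
]

META_COLUMNS = ("specimen_id", "clade", "taxon", "lat", "lon", "elevation_m")


def read_traits(path) -> tuple[TraitMatrix, pd.DataFrame]:
    """Read a trait CSV; returns the matrix plus the metadata columns.

    Trait columns are every column outside the metadata set.  Observed trait
    values must be strictly positive (they are log-transformed downstream);
    offending rows are reported.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "specimen_id" not in df.columns:
        raise ValueError("trait CSV must have a 'specimen_id' column")
    trait_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not trait_cols:
        raise ValueError("trait CSV has no trait columns")
    vals = df[trait_cols].to_numpy(dtype=float)
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        rows = (np.flatnonzero(bad.any(axis=1)) + 2).tolist()  # 1-based + header
        raise ValueError(
            f"non-positive trait values (log undefined) in CSV line(s) {rows}"
        )
    ids = df["specimen_id"].astype(str).tolist()
    meta_cols = [c for c in META_COLUMNS if c in df.columns]
    meta = df[meta_cols].copy()
    meta.index = ids
    return TraitMatrix(vals, ids, trait_cols), meta


def write_traits(traits: TraitMatrix, path, meta: pd.DataFrame | None = None) -> None:
    df = traits.to_frame()
    df.index.name = "specimen_id"
    if meta is not None:
        extra = meta.reindex(df.index).drop(columns=["specimen_id"], errors="ignore")
        df = pd.concat([extra, df], axis=1)
    df.reset_index().to_csv(path, index=False)


def read_vcf(path) -> tuple[GenotypeMatrix, dict]:
    """Read biallelic SNPs from a VCF 4.2 with GT calls.

    Dosage coding 0/1/2 (phase-agnostic), ``./.`` kept as missing.  Sites
    with more than one ALT allele are skipped; when several SNPs share a
    locus tag (the CHROM field), only the first is retained.  Both filters
    are counted in the returned log dict.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    locus_ids = []
    seen_loci: set[str] = set()
    skipped_multiallelic = 0
    dropped_extra_snps = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped_multiallelic += 1
            continue
        locus = rec.CHROM
        if locus in seen_loci:
            dropped_extra_snps += 1
            continue
        seen_loci.add(locus)
        g = rec.gt_types.astype(np.int8)  # 0,1,2; 3 = unknown under gts012
        g[g == 3] = -1
        rows.append(g)
        locus_ids.append(rec.ID if rec.ID not in (None, ".") else f"{locus}:{rec.POS}")
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic sites in {path}")
    values = np.stack(rows, axis=1)
    log = {"skipped_multiallelic": skipped_multiallelic, "dropped_extra_snps": dropped_extra_snps}
    return GenotypeMatrix(values, samples, locus_ids), log


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2: one contig per locus, GT-only, ./. missing."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=speciesdelim\n")
        for locus in g.locus_ids:
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.specimen_ids) + "\n")
        for j, locus in enumerate(g.locus_ids):
            gts = "\t".join(code[int(v)] for v in g.values[:, j])
            fh.write(f"{locus}\t1\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_012(path) -> GenotypeMatrix:
    """Read a 012-coded TSV matrix (rows = specimens, -1 = missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        df.to_numpy(dtype=np.int8), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def write_012(g: GenotypeMatrix, path) -> None:
    df = g.to_frame()
    df.index.name = "specimen_id"
    df.to_csv(path, sep="\t")


def read_ranges(path) -> SpeciesBoxSet:
    """Read a per-species trait range CSV (taxon, trait, min, max)."""
    return SpeciesBoxSet.from_frame(pd.read_csv(path, float_precision="round_trip"))


def write_ranges(boxes: SpeciesBoxSet, path) -> None:
    boxes.to_frame().to_csv(path, index=False)


def write_assignments(assignments: pd.Series, path, group_col: str = "group") -> None:
    df = pd.DataFrame({"specimen_id": assignments.index, group_col: assignments.values})
    df.to_csv(path, sep="\t", index=False)


def read_assignments_tsv(path, group_col: str | None = None) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "specimen_id" not in df.columns:
        raise ValueError("assignment TSV must have a 'specimen_id' column")
    col = group_col or [c for c in df.columns if c != "specimen_id"][0]
    if df["specimen_id"].duplicated().any():
        raise ValueError("duplicate specimen ids in assignment TSV")
    return pd.Series(df[col].values, index=df["specimen_id"].values, name=col)
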
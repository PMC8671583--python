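"""End-to-end per-clade orchestration.

A run takes trait and genotype files (plus taxonomic range boxes), splits
specimens by clade, and within each clade performs: the hypercube audit,
phenogroup delimitation (log -> robust PCA -> forward selection -> GMM
sweep vs a-priori models), genogroup delimitation (shared-allele distance
-> NMDS -> GMM sweep), and integration with correspondence counts.  Every
output directory carries a manifest recording the config hash, seeds, and
input checksums so identical configs reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hypercube, integrate, io, pheno
from .geno import delimit_gc, nmds, shared_allele_distance
from .mixture import FAMILIES

logger = logging.getLogger("speciesdelim")

__all__ = ["RunConfig", "run_pipeline", "CladeResult"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    traits_path: str
    vcf_path: str | None = None
    geno012_path: str | None = None
    ranges_path: str | None = None
    out_dir: str = "speciesdelim_out"
    clade_column: str = "clade"
    n_taxa: dict[str, int] = field(default_factory=dict)  # clade -> n taxonomic species
    families: tuple[str, ...] = FAMILIES
    criterion: str = "bic"
    nmds_dims: int = 2
    stress_threshold: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in ("bic", "icl"):
            raise ValueError("criterion must be 'bic' or 'icl'")
        if self.nmds_dims < 1:
            raise ValueError("nmds_dims must be >= 1")
        for clade, n in self.n_taxa.items():
            if int(n) < 1:
                raise ValueError(f"n_taxa for clade {clade!r} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if "families" in payload:
            payload["families"] = tuple(payload["families"])
        return cls(**payload)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class CladeResult:
    clade: str
    audit: hypercube.MatchReport | None
    pheno_ranking: pheno.ModelRanking
    pheno_assignments: pd.Series
    geno_sweep_stress: float
    geno_assignments: pd.Series
    cells: list[integrate.SpeciesCell]
    correspondence: integrate.CorrespondenceReport
    contingency: integrate.ContingencyTable


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _delimit_clade(config, clade, traits, meta, genotypes, boxes, seed):
    """All stages for one clade; returns a CladeResult."""
    taxa = meta["taxon"].astype(str)
    n_taxa = int(config.n_taxa.get(clade, taxa.nunique()))

    audit = None
    if boxes is not None:
        clade_boxes = hypercube.SpeciesBoxSet(
            {s: boxes[s] for s in boxes.species if s in set(taxa)}
        )
        if len(clade_boxes):
            audit = hypercube.audit_clade(traits, taxa, clade_boxes)

    # phenotype: complete cases, log scale, robust rotation, selection, sweep
    complete = traits.complete_cases()
    rotated = pheno.robust_pca(complete.log_values())
    selected, _ = pheno.select_variables(
        rotated, k_grid=range(2, pheno.k_grid_upper(n_taxa) + 1), seed=seed
    )
    naive = pheno.fit_naive(rotated, n_taxa, config.families, config.criterion,
                            seed=seed, components=selected)
    tax_labels = taxa.loc[complete.specimen_ids]
    taxonomy_fit = pheno.fit_apriori(rotated, tax_labels, config.families, components=selected)
    ranking = pheno.compare_pheno_models(
        {"Naive": naive.best, "Taxonomy": taxonomy_fit}, config.criterion
    )
    pheno_assign = pd.Series(
        [f"P{j + 1}" for j in naive.best.labels], index=complete.specimen_ids, name="phenogroup"
    )

    # genotype: distance -> NMDS -> GC sweep
    keep = [i for i, s in enumerate(genotypes.specimen_ids) if s in set(meta.index)]
    sub = io.GenotypeMatrix(
        genotypes.values[keep],
        [genotypes.specimen_ids[i] for i in keep],
        genotypes.locus_ids,
    )
    dist = shared_allele_distance(sub)
    embedding = nmds(dist, dims=config.nmds_dims, seed=seed,
                     stress_threshold=config.stress_threshold)
    geno_sweep, geno_assign = delimit_gc(embedding, n_taxa, config.families,
                                         config.criterion, seed=seed)

    table = integrate.build_contingency(pheno_assign, geno_assign)
    cells = integrate.classify_cells(table)
    report = integrate.correspondence_summary(taxa, pheno_assign, geno_assign)
    return CladeResult(
        clade=clade,
        audit=audit,
        pheno_ranking=ranking,
        pheno_assignments=pheno_assign,
        geno_sweep_stress=embedding.stress,
        geno_assignments=geno_assign,
        cells=cells,
        correspondence=report,
        contingency=table,
    )


def run_pipeline(config: RunConfig) -> dict[str, CladeResult]:
    """Run every clade; failures abort that clade only.  Writes per-clade
    TSV/JSON reports and a run manifest under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traits_all, meta_all = io.read_traits(config.traits_path)
    if config.vcf_path:
        genotypes, _ = io.read_vcf(config.vcf_path)
    elif config.geno012_path:
        genotypes = io.read_012(config.geno012_path)
    else:
        raise ValueError("config needs vcf_path or geno012_path")
    boxes = io.read_ranges(config.ranges_path) if config.ranges_path else None

    clades = (
        sorted(meta_all[config.clade_column].astype(str).unique())
        if config.clade_column in meta_all.columns
        else ["all"]
    )
    results: dict[str, CladeResult] = {}
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "inputs": {
            p: _checksum(p)
            for p in (config.traits_path, config.vcf_path, config.geno012_path, config.ranges_path)
            if p
        },
        "clades": {},
    }
    for clade in clades:
        t0 = time.time()
        try:
            if clade == "all":
                mask = np.ones(traits_all.n_specimens, dtype=bool)
            else:
                mask = (meta_all[config.clade_column].astype(str) == clade).to_numpy()
            idx = np.flatnonzero(mask)
            traits = traits_all.subset(idx)
            meta = meta_all.iloc[idx]
            result = _delimit_clade(config, clade, traits, meta, genotypes, boxes, config.seed)
        except Exception as exc:  # one clade failing must not sink the others
            logger.error("clade %s failed: %s", clade, exc)
            manifest["clades"][clade] = {"status": "failed", "error": str(exc)}
            continue
        results[clade] = result
        clade_dir = out / f"clade_{clade}"
        _write_clade(clade_dir, result, config)
        manifest["clades"][clade] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 2),
            "n_phenogroups": result.correspondence.n_phenogroups,
            "n_genogroups": result.correspondence.n_genogroups,
            "outputs": {
                p.name: _checksum(p) for p in sorted(clade_dir.glob("*.tsv"))
            },
        }
        logger.info("clade %s done in %.1fs", clade, time.time() - t0)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return results


def _write_clade(clade_dir: Path, r: CladeResult, config: RunConfig) -> None:
    clade_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    r.pheno_ranking.table.to_csv(clade_dir / "pheno_ranking.tsv", sep="\t", index=False)
    io.write_assignments(r.pheno_assignments, clade_dir / "phenogroups.tsv", "phenogroup")
    io.write_assignments(r.geno_assignments, clade_dir / "genogroups.tsv", "genogroup")
    r.contingency.counts.to_csv(clade_dir / "contingency.tsv", sep="\t")
    cells = pd.DataFrame([dataclasses.asdict(c) for c in r.cells])
    cells.to_csv(clade_dir / "species_cells.tsv", sep="\t", index=False)
    if r.audit is not None:
        r.audit.per_specimen.to_csv(clade_dir / "audit_specimens.tsv", sep="\t", index=False)
    report = {
        **stamp,
        "clade": r.clade,
        "nmds_stress": r.geno_sweep_stress,
        "correspondence": r.correspondence.to_row(),
        "species_cells": [dataclasses.asdict(c) for c in r.cells],
        "audit_summary": r.audit.summary if r.audit is not None else None,
        "unknown_pheno_only": r.contingency.unknown_pheno_only,
        "unknown_geno_only": r.contingency.unknown_geno_only,
    }
    with open(clade_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
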
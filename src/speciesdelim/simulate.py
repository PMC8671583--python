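"""Synthetic clades with known phenotypic and genotypic group structure.

The generator emulates the statistical structure the delimitation pipeline
assumes about a clade of flowering plants:

* **Traits** — within a phenogroup, continuous measurements are multivariate
  log-normal: specimens are drawn from the group's Gaussian on the log scale
  and exponentiated to the raw measurement scale (the Fisherian assumption
  that conspecific variation is normally distributed, on the scale on which
  analysis happens).
* **Genotypes** — a Balding–Nichols island model: each locus draws an
  ancestral allele frequency, each deme (genogroup) perturbs it through a
  Beta distribution whose concentration is governed by an Fst-like
  ``divergence`` parameter, and diploid genotypes are sampled under
  within-deme Hardy–Weinberg equilibrium.
* **Taxonomy** — each specimen belongs to a named species; ``label_noise``
  relabels a fraction of specimens uniformly among the clade's other species,
  producing controlled taxonomy/phenogroup discordance.
* **Range boxes** — per-species trait min/max tables are derived from a
  designated "described" subsample at configurable coverage quantiles,
  mimicking monograph ranges tabulated from specimens other than those later
  measured.
* **Geography** — per-species 2-D centres with isotropic Gaussian scatter,
  in decimal degrees, plus an elevation column.

Missingness is missing-completely-at-random throughout.  Species may share a
phenogroup or a genogroup (``phenogroup_of_species`` / ``genogroup_of_species``),
which is how cryptic-species scenarios are scripted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, SpeciesBoxSet, TraitMatrix

__all__ = [
    "CladeScenario",
    "SyntheticClade",
    "simulate_traits",
    "simulate_genotypes",
    "derive_taxonomic_ranges",
    "simulate_clade",
    "separated_scenario",
    "cryptic_scenario",
]


@dataclass
class CladeScenario:
    """Full specification of one simulated clade.

    ``trait_means``/``trait_covariances`` are indexed by *phenogroup* and
    ``divergence`` structures *genogroups*; by default each species is its own
    phenogroup and genogroup (the identity mappings), matching a clade of
    "good" species.
    """

    n_species: int
    specimens_per_species: Sequence[int]
    trait_means: np.ndarray  # (n_phenogroups, n_traits), log scale
    trait_covariances: np.ndarray  # (n_phenogroups, n_traits, n_traits)
    covariance_family: str = "full-varying"
    n_loci: int = 1000
    divergence: float | Sequence[float] = 0.2  # scalar, or one Fst per deme
    genotype_model: str = "island"  # "island" (Balding–Nichols) or "spatial"
    spatial_gradient_sd: float = 1.2  # per-locus allele-frequency cline strength
    spatial_within_sd: float = 0.09  # within-deme scatter of latent positions
    missing_rate_traits: float = 0.0
    missing_rate_snps: float = 0.0
    label_noise: float = 0.0
    phenogroup_of_species: Sequence[int] | None = None
    genogroup_of_species: Sequence[int] | None = None
    geography_centers: np.ndarray | None = None  # (n_species, 2) lat, lon
    geography_spread: float = 0.5  # degrees
    elevation_range: tuple[float, float] = (500.0, 3500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        self.specimens_per_species = list(self.specimens_per_species)
        if len(self.specimens_per_species) != self.n_species:
            raise ValueError("need one specimen count per species")
        if any(c < 1 for c in self.specimens_per_species):
            raise ValueError("specimen counts must be positive")
        div = np.atleast_1d(np.asarray(self.divergence, dtype=float))
        if ((div < 0.0) | (div >= 1.0)).any():
            raise ValueError(f"divergence must lie in [0, 1); got {self.divergence}")
        if self.genotype_model not in ("island", "spatial"):
            raise ValueError(
                f"genotype_model must be 'island' or 'spatial'; got {self.genotype_model!r}"
            )
        if self.spatial_gradient_sd < 0 or self.spatial_within_sd < 0:
            raise ValueError("spatial model scales must be non-negative")
        for name in ("missing_rate_traits", "missing_rate_snps", "label_noise"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {r}")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.phenogroup_of_species is None:
            self.phenogroup_of_species = list(range(self.n_species))
        if self.genogroup_of_species is None:
            self.genogroup_of_species = list(range(self.n_species))
        self.phenogroup_of_species = [int(g) for g in self.phenogroup_of_species]
        self.genogroup_of_species = [int(g) for g in self.genogroup_of_species]
        self.trait_means = np.atleast_2d(np.asarray(self.trait_means, dtype=float))
        self.trait_covariances = np.asarray(self.trait_covariances, dtype=float)
        if self.trait_covariances.ndim == 2:
            self.trait_covariances = self.trait_covariances[None]
        n_pheno = self.n_phenogroups
        if self.trait_means.shape[0] != n_pheno or self.trait_covariances.shape[0] != n_pheno:
            raise ValueError(
                f"trait_means/trait_covariances must cover all {n_pheno} phenogroups"
            )
        for g in range(n_pheno):
            cov = self.trait_covariances[g]
            if not np.allclose(cov, cov.T):
                raise ValueError(f"covariance for phenogroup {g} is not symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError(f"covariance for phenogroup {g} is not positive definite")
        if self.geography_centers is None:
            rng = np.random.default_rng(self.seed ^ 0x5EED)
            self.geography_centers = np.column_stack(
                [rng.uniform(-40, 10, self.n_species), rng.uniform(-80, -60, self.n_species)]
            )
        self.geography_centers = np.asarray(self.geography_centers, dtype=float)

    @property
    def n_phenogroups(self) -> int:
        return max(self.phenogroup_of_species) + 1

    @property
    def n_genogroups(self) -> int:
        return max(self.genogroup_of_species) + 1

    @property
    def n_traits(self) -> int:
        return self.trait_means.shape[1]

    @property
    def n_specimens(self) -> int:
        return sum(self.specimens_per_species)

    def species_names(self) -> list[str]:
        return [f"species_{chr(ord('A') + i)}" if i < 26 else f"species_{i}" for i in range(self.n_species)]

    def specimen_ids(self) -> list[str]:
        return [f"sp{i:04d}" for i in range(self.n_specimens)]

    def species_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_species), self.specimens_per_species)

    def to_yaml(self, path) -> None:
        payload = {
            "n_species": self.n_species,
            "specimens_per_species": list(map(int, self.specimens_per_species)),
            "trait_means": self.trait_means.tolist(),
            "trait_covariances": self.trait_covariances.tolist(),
            "covariance_family": self.covariance_family,
            "n_loci": int(self.n_loci),
            "divergence": (
                float(self.divergence)
                if np.isscalar(self.divergence)
                else [float(v) for v in np.atleast_1d(self.divergence)]
            ),
            "genotype_model": self.genotype_model,
            "spatial_gradient_sd": float(self.spatial_gradient_sd),
            "spatial_within_sd": float(self.spatial_within_sd),
            "missing_rate_traits": float(self.missing_rate_traits),
            "missing_rate_snps": float(self.missing_rate_snps),
            "label_noise": float(self.label_noise),
            "phenogroup_of_species": list(map(int, self.phenogroup_of_species)),
            "genogroup_of_species": list(map(int, self.genogroup_of_species)),
            "geography_centers": self.geography_centers.tolist(),
            "geography_spread": float(self.geography_spread),
            "elevation_range": list(self.elevation_range),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CladeScenario":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["trait_means"] = np.asarray(payload["trait_means"], dtype=float)
        payload["trait_covariances"] = np.asarray(payload["trait_covariances"], dtype=float)
        payload["geography_centers"] = np.asarray(payload["geography_centers"], dtype=float)
        payload["elevation_range"] = tuple(payload["elevation_range"])
        return cls(**payload)


@dataclass
class SyntheticClade:
    """One simulated clade with its ground truth."""

    traits: TraitMatrix
    genotypes: GenotypeMatrix
    taxonomy_labels: pd.Series  # specimen_id -> species name (possibly noisy)
    true_species: pd.Series
    true_phenogroup: pd.Series
    true_genogroup: pd.Series
    boxes: SpeciesBoxSet
    geography: pd.DataFrame  # specimen_id, lat, lon, elevation_m

    def __post_init__(self) -> None:
        ids = list(self.traits.specimen_ids)
        for name in ("taxonomy_labels", "true_species", "true_phenogroup", "true_genogroup"):
            s = getattr(self, name)
            if list(s.index) != ids:
                raise ValueError(f"{name} is not indexed by the clade's specimen ids")
        if self.genotypes.specimen_ids != ids:
            raise ValueError("genotype matrix is not indexed by the clade's specimen ids")


def simulate_traits(scenario: CladeScenario, rng: np.random.Generator | None = None):
    """Draw the trait matrix (raw scale) and the true phenogroup labels.

    Each specimen is sampled from its phenogroup's multivariate Gaussian on
    the log scale and exponentiated; the requested fraction of cells is then
    masked missing completely at random.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    sp_idx = scenario.species_index()
    pheno = np.asarray(scenario.phenogroup_of_species)[sp_idx]
    n, d = scenario.n_specimens, scenario.n_traits
    log_vals = np.empty((n, d))
    for g in range(scenario.n_phenogroups):
        members = np.flatnonzero(pheno == g)
        if members.size:
            log_vals[members] = rng.multivariate_normal(
                scenario.trait_means[g], scenario.trait_covariances[g], size=members.size,
                method="cholesky",
            )
    raw = np.exp(log_vals)
    if scenario.missing_rate_traits > 0:
        mask = rng.random((n, d)) < scenario.missing_rate_traits
        raw[mask] = np.nan
    ids = scenario.specimen_ids()
    traits = TraitMatrix(raw, ids, [f"trait_{j + 1}" for j in range(d)])
    labels = pd.Series([f"P{g + 1}" for g in pheno], index=ids, name="true_phenogroup")
    return traits, labels


def simulate_genotypes(scenario: CladeScenario, rng: np.random.Generator | None = None):
    """Draw the SNP matrix and the true genogroup (deme) labels.

    Two generating models:

    * ``"island"`` (default) — Balding–Nichols: ancestral frequency
      p ~ Uniform(0.05, 0.95) per locus; for divergence F > 0 each deme
      draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) (mean p, and
      Fst ≈ F between demes); F = 0 collapses to the ancestral frequency.
      ``divergence`` may be a single value (classic symmetric model, all
      demes mutually equidistant in expectation) or one value per deme.
    * ``"spatial"`` — isolation-by-distance on a latent plane: demes sit on
      the unit circle, each specimen's latent position is its deme centre
      plus N(0, ``spatial_within_sd``²) scatter, and every locus carries a
      2-D logit-frequency cline with slope ~ N(0, ``spatial_gradient_sd``²)
      per axis.  Between-specimen genetic distance then grows with latent
      distance, giving the low-stress two-dimensional ordination structure
      that geographically structured clades show (a symmetric island model
      with many demes has no faithful 2-D representation).

    Genotypes are Binomial(2, p) under within-deme Hardy–Weinberg.
    Monomorphic loci may arise and are flagged on the matrix.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    sp_idx = scenario.species_index()
    deme = np.asarray(scenario.genogroup_of_species)[sp_idx]
    n, L = scenario.n_specimens, scenario.n_loci
    n_demes = scenario.n_genogroups
    if scenario.genotype_model == "island":
        F = np.broadcast_to(
            np.atleast_1d(np.asarray(scenario.divergence, dtype=float)), (n_demes,)
        )
        p_anc = rng.uniform(0.05, 0.95, size=L)
        p_deme = np.empty((n_demes, L))
        for d_idx in range(n_demes):
            f = F[d_idx]
            if f > 0:
                c = (1.0 - f) / f
                a = np.clip(p_anc * c, 1e-8, None)
                b = np.clip((1.0 - p_anc) * c, 1e-8, None)
                p_deme[d_idx] = rng.beta(a, b)
            else:
                p_deme[d_idx] = p_anc
        p_ind = p_deme[deme, :]
    else:  # spatial
        p_anc = rng.uniform(0.1, 0.9, size=L)
        angles = 2 * np.pi * np.arange(n_demes) / max(n_demes, 1)
        centers = (
            np.column_stack([np.cos(angles), np.sin(angles)])
            if n_demes > 1
            else np.zeros((1, 2))
        )
        latent = centers[deme] + rng.normal(0.0, scenario.spatial_within_sd, size=(n, 2))
        slopes = rng.normal(0.0, scenario.spatial_gradient_sd, size=(L, 2))
        logits = np.log(p_anc / (1.0 - p_anc))[None, :] + latent @ slopes.T
        p_ind = 1.0 / (1.0 + np.exp(-logits))
    geno = rng.binomial(2, p_ind).astype(np.int8)
    if scenario.missing_rate_snps > 0:
        mask = rng.random((n, L)) < scenario.missing_rate_snps
        geno[mask] = -1
    ids = scenario.specimen_ids()
    gm = GenotypeMatrix(geno, ids, [f"locus_{j + 1}" for j in range(L)])
    labels = pd.Series([f"G{g + 1}" for g in deme], index=ids, name="true_genogroup")
    return gm, labels


def derive_taxonomic_ranges(
    traits: TraitMatrix,
    labels,
    coverage: tuple[float, float] = (0.0, 1.0),
    described_subset: Sequence[str] | None = None,
) -> SpeciesBoxSet:
    """Build monograph-style per-species trait range boxes.

    Per species and trait, min/max are the ``coverage`` quantiles (default
    (0, 1) = the full observed range) computed over a designated "described"
    subsample of complete specimens, so that matching-prediction on held-out
    specimens can legitimately fail.  Every species needs at least two
    complete described specimens.
    """
    lo_q, hi_q = coverage
    if not (0.0 <= lo_q < hi_q <= 1.0):
        raise ValueError(f"coverage quantiles must satisfy 0 <= lo < hi <= 1; got {coverage}")
    labels = pd.Series(labels, index=traits.specimen_ids) if not isinstance(labels, pd.Series) else labels
    df = traits.to_frame()
    if described_subset is not None:
        df = df.loc[list(described_subset)]
    df = df.dropna()
    rows = []
    for taxon in pd.unique(labels.astype(str)):
        members = df.loc[df.index.intersection(labels.index[labels.astype(str) == taxon])]
        if len(members) < 2:
            raise ValueError(
                f"species {taxon!r} has {len(members)} complete described specimens; need >= 2"
            )
        lo = members.quantile(lo_q)
        hi = members.quantile(hi_q)
        for t in traits.trait_names:
            rows.append({"taxon": taxon, "trait": t, "min": lo[t], "max": hi[t]})
    return SpeciesBoxSet.from_frame(pd.DataFrame(rows))


def simulate_clade(scenario: CladeScenario, *, described_fraction: float = 0.5,
                   coverage: tuple[float, float] = (0.0, 1.0)) -> SyntheticClade:
    """Generate a full clade: traits, genotypes, noisy taxonomy, boxes, geography.

    The range boxes are derived from a random "described" half of the complete
    specimens (per ``described_fraction``) using the true species labels, so
    box construction never sees the label noise.
    """
    rng = np.random.default_rng(scenario.seed)
    traits, pheno = simulate_traits(scenario, rng)
    genotypes, geno = simulate_genotypes(scenario, rng)
    ids = scenario.specimen_ids()
    sp_idx = scenario.species_index()
    names = scenario.species_names()
    true_species = pd.Series([names[i] for i in sp_idx], index=ids, name="true_species")

    taxonomy = true_species.copy().rename("taxon")
    if scenario.label_noise > 0 and scenario.n_species > 1:
        flip = rng.random(len(ids)) < scenario.label_noise
        for pos in np.flatnonzero(flip):
            others = [s for s in names if s != taxonomy.iloc[pos]]
            taxonomy.iloc[pos] = others[rng.integers(len(others))]

    # stratified "described" subsample: at least 2 complete specimens per
    # species, then fill to the requested fraction at random
    complete = traits.complete_case_ids()
    by_species: dict[str, list[str]] = {}
    for sid in complete:
        by_species.setdefault(true_species[sid], []).append(sid)
    described: list[str] = []
    for members in by_species.values():
        take = rng.permutation(len(members))[:2]
        described.extend(members[i] for i in take)
    pool = [sid for sid in complete if sid not in set(described)]
    n_extra = int(round(described_fraction * len(complete))) - len(described)
    if n_extra > 0 and pool:
        described.extend(np.array(pool)[rng.permutation(len(pool))[:n_extra]])
    boxes = derive_taxonomic_ranges(traits, true_species, coverage=coverage, described_subset=described)

    centers = scenario.geography_centers[sp_idx]
    coords = centers + rng.normal(0.0, scenario.geography_spread, size=centers.shape)
    elev = rng.uniform(*scenario.elevation_range, size=len(ids))
    geography = pd.DataFrame(
        {"lat": coords[:, 0], "lon": coords[:, 1], "elevation_m": elev}, index=ids
    )
    return SyntheticClade(
        traits=traits,
        genotypes=genotypes,
        taxonomy_labels=taxonomy,
        true_species=true_species,
        true_phenogroup=pheno,
        true_genogroup=geno,
        boxes=boxes,
        geography=geography,
    )


def cryptic_scenario(
    n_per_species: int = 30,
    n_traits: int = 10,
    separation: float = 8.0,
    n_loci: int = 1200,
    seed: int = 0,
) -> CladeScenario:
    """Scripted clade with a planned mix of species kinds.

    Seven species map onto six phenogroups and six genogroups so the true
    contingency table holds three *good* cells (one phenogroup ↔ one
    genogroup), one phenotypic-cryptic complex (one phenogroup hiding two
    genogroups → two phenotypic_cryptic cells) and one genetic-cryptic
    complex (one genogroup hiding two phenogroups → two genetic_cryptic
    cells).  Group mean differences are low-rank, as morphological
    covariation tends to be: the six phenogroup means sit on a hexagon in
    the plane of the first two (log) traits, adjacent groups ``separation``
    within-group standard deviations apart, with the remaining traits
    carrying no group signal.  Genotypes follow the spatial
    isolation-by-distance model: its latent plane gives the genotype
    distances a faithful low-stress two-dimensional ordination, so the
    genotypic-cluster chain can recover all six demes — a symmetric island
    model with six demes cannot be embedded in two dimensions without
    distortion.
    """
    pheno_of_species = [0, 1, 2, 3, 3, 4, 5]
    geno_of_species = [0, 1, 2, 3, 4, 5, 5]
    n_pheno = 6
    sd = 0.25
    means = np.full((n_pheno, n_traits), 1.0)
    radius = separation * sd  # hexagon side length = radius
    for g in range(n_pheno):
        angle = 2 * math.pi * g / n_pheno
        means[g, 0] += radius * math.cos(angle)
        means[g, 1] += radius * math.sin(angle)
    covs = np.repeat(np.eye(n_traits)[None] * sd**2, n_pheno, axis=0)
    return CladeScenario(
        n_species=7,
        specimens_per_species=[n_per_species] * 7,
        trait_means=means,
        trait_covariances=covs,
        n_loci=n_loci,
        genotype_model="spatial",
        spatial_within_sd=0.12,
        phenogroup_of_species=pheno_of_species,
        genogroup_of_species=geno_of_species,
        seed=seed,
    )


def separated_scenario(
    n_species: int = 3,
    n_per_species: int = 40,
    n_traits: int = 10,
    separation: float = 6.0,
    n_loci: int = 1000,
    divergence: float = 0.3,
    seed: int = 0,
    **kwargs,
) -> CladeScenario:
    """Convenience scenario: species separated by ``separation`` within-group
    standard deviations along distinct trait axes (log scale, unit variance).

    Defaults mirror a mid-sized clade: a handful of species, tens of
    specimens each (clade totals in the tens-to-hundreds), around a thousand
    SNP loci and moderate divergence.
    """
    sd = 0.25
    means = np.full((n_species, n_traits), 1.0)  # log-scale baseline
    # each later group offset along its own trait axis: pairwise distance
    # >= separation within-group standard deviations
    for g in range(1, n_species):
        means[g, (g - 1) % n_traits] += separation * sd
    covs = np.repeat(np.eye(n_traits)[None] * sd**2, n_species, axis=0)
    return CladeScenario(
        n_species=n_species,
        specimens_per_species=[n_per_species] * n_species,
        trait_means=means,
        trait_covariances=covs,
        n_loci=n_loci,
        divergence=divergence,
        seed=seed,
        **kwargs,
    )
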
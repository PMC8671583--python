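"""Genogroup delimitation under the genotypic-clusters (GC) model.

Two or more clusters of genotypes in a co-occurring sample — groups with a
deficit of intermediates — are evidence for more than one species.  The
chain here is:

1. **shared-allele distance** between diploid individuals:
   D = 1 − mean over pairwise-complete loci of the proportion of alleles
   the two genotypes share under optimal pairing (so 0/1/2 dosage pairs map
   to ps ∈ {1, 0.5, 0, 1, 0.5, 1} for (0,0),(0,1),(0,2),(1,1),(1,2),(2,2));
   loci missing in either individual are dropped pair by pair.
2. **non-metric multidimensional scaling** of D to (by default) two
   dimensions, minimising Kruskal stress-1; a warning is emitted when the
   final stress is at or above the 15% retention threshold.
3. a **Gaussian-mixture sweep** on the embedding (K = 1..ceil(n + n/2),
   all covariance families, best by BIC) whose components are the
   genogroups.

Delimitations from external tools enter only as assignment tables
(:func:`import_assignments`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .datatypes import GenotypeMatrix, check_assignment_series
from .mixture import FAMILIES
from .pheno import SweepResult, _sweep, k_grid_upper

__all__ = [
    "DistanceMatrix",
    "EmbeddingResult",
    "shared_allele_distance",
    "nmds",
    "delimit_gc",
    "import_assignments",
]


@dataclass
class DistanceMatrix:
    """Symmetric specimen distances in [0,1] plus per-pair locus counts."""

    values: np.ndarray
    specimen_ids: list[str]
    loci_used: np.ndarray  # per-pair count of pairwise-complete loci

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.specimen_ids):
            raise ValueError("distance matrix shape inconsistent with specimen ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.diag(v).any():
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("shared-allele distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.specimen_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.specimen_ids, columns=self.specimen_ids)


def shared_allele_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance with pairwise deletion of missing loci.

    For dosage codes a, b ∈ {0,1,2} the shared-allele proportion under
    optimal pairing is ps = 1 − |a − b| / 2; D = 1 − mean(ps).  Every pair
    must share at least one non-missing locus.
    """
    if g.n_specimens < 2:
        raise ValueError("need at least two specimens")
    vals = g.values.astype(float)
    vals[g.missing_mask] = np.nan
    n = g.n_specimens
    D = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = np.abs(vals[i + 1:] - vals[i])  # NaN where either is missing
        used = (~np.isnan(diff)).sum(axis=1)
        if (used == 0).any():
            j = i + 1 + int(np.argmax(used == 0))
            raise ValueError(
                f"specimens {g.specimen_ids[i]!r} and {g.specimen_ids[j]!r} "
                "share no non-missing locus"
            )
        ps_mean = 1.0 - np.nanmean(diff, axis=1) / 2.0
        D[i, i + 1:] = 1.0 - ps_mean
        D[i + 1:, i] = D[i, i + 1:]
        counts[i, i + 1:] = used
        counts[i + 1:, i] = used
    # guard against float round-off outside [0,1]
    np.clip(D, 0.0, 1.0, out=D)
    return DistanceMatrix(values=D, specimen_ids=list(g.specimen_ids), loci_used=counts)


@dataclass
class EmbeddingResult:
    """NMDS configuration: coordinates, final Kruskal stress-1, bookkeeping."""

    coords: np.ndarray
    stress: float
    n_iter: int
    seed: int | None
    specimen_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [f"nmds_{j + 1}" for j in range(self.coords.shape[1])]
        idx = self.specimen_ids if self.specimen_ids is not None else range(len(self.coords))
        return pd.DataFrame(self.coords, index=idx, columns=cols)


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _nmds_once(delta: np.ndarray, dims: int, x0: np.ndarray, max_iter: int, tol: float):
    n = delta.shape[0]
    iu = np.triu_indices(n, 1)
    dvec = delta[iu]
    # primary tie approach: within tied dissimilarities, order by current
    # configuration distance so ties impose no constraint
    x = x0.copy()
    last = np.inf
    stress = np.inf
    it = 0
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    for it in range(1, max_iter + 1):
        d = pdist(x)
        order = np.lexsort((d, dvec))
        dhat_sorted = iso.fit_transform(np.arange(dvec.size), d[order])
        dhat = np.empty_like(d)
        dhat[order] = dhat_sorted
        stress = _kruskal_stress(d, dhat)
        if np.isfinite(last) and abs(last - stress) < tol * max(last, 1e-12):
            break
        last = stress
        # Guttman transform toward the disparities; renormalise the
        # disparities first (stress-1 is scale-invariant, so without this
        # the configuration can shrink toward the origin unnoticed)
        ss = (dhat**2).sum()
        if ss <= 0:
            break
        dhat = dhat * np.sqrt(dvec.size / ss)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = squareform(-ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        x = (B @ x) / n
    return x, stress, it


def nmds(
    dist: DistanceMatrix | np.ndarray,
    dims: int = 2,
    seed: int | None = 0,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
    stress_threshold: float = 0.15,
) -> EmbeddingResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Initialised from classical (metric) scaling plus ``n_restarts`` random
    starts; the lowest-stress configuration wins and is centred at the
    origin.  NMDS depends on the input distances only through their ranks.
    A warning fires when the final stress is ≥ ``stress_threshold``
    (the retention rule used to accept a two-dimensional embedding).
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.values
        ids = dist.specimen_ids
    else:
        D = np.asarray(dist, dtype=float)
        ids = None
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = D.shape[0]
    offdiag = D[np.triu_indices(n, 1)]
    if offdiag.size == 0 or (offdiag == 0).all():
        raise ValueError("all pairwise distances are zero; nothing to embed")

    rng = np.random.default_rng(seed)
    starts = [_classical_mds(D, dims)]
    scale = offdiag.mean()
    for _ in range(n_restarts):
        starts.append(rng.normal(scale=scale, size=(n, dims)))
    best = None
    for x0 in starts:
        x, stress, it = _nmds_once(D, dims, x0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, it)
    x, stress, it = best
    x = x - x.mean(axis=0)
    if stress >= stress_threshold:
        warnings.warn(
            f"NMDS stress {stress:.3f} >= {stress_threshold:.2f}: a {dims}-D embedding "
            "may not faithfully represent the distances",
            stacklevel=2,
        )
    return EmbeddingResult(coords=x, stress=stress, n_iter=it, seed=seed, specimen_ids=ids)


def delimit_gc(
    embedding: EmbeddingResult,
    n_taxa: int,
    families=FAMILIES,
    criterion: str = "bic",
    seed: int = 0,
) -> tuple[SweepResult, pd.Series]:
    """Genotypic-clusters delimitation: GMM sweep on the NMDS embedding.

    Returns the sweep result and the genogroup assignment series
    (``G1``, ``G2``, ... by component index).
    """
    kmax = k_grid_upper(n_taxa)
    sweep = _sweep(embedding.coords, range(1, kmax + 1), families, seed, criterion, "GC")
    ids = embedding.specimen_ids if embedding.specimen_ids is not None else list(range(len(embedding.coords)))
    assignments = pd.Series(
        [f"G{j + 1}" for j in sweep.best.labels], index=ids, name="genogroup"
    )
    return sweep, assignments


def import_assignments(path, known_ids=None) -> tuple[pd.Series, list[str]]:
    """Read an external delimitation (e.g. from tree- or coalescent-based
    tools) as a two-column TSV ``specimen_id<TAB>group``.

    Returns the assignment series restricted to ``known_ids`` (when given)
    and the list of unmatched ids; duplicate specimen ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["specimen_id", "group"]
    if list(df.columns[:2]) != required:
        raise ValueError(f"assignment table must have header {required}; got {list(df.columns)}")
    if df["specimen_id"].duplicated().any():
        dupes = df.loc[df["specimen_id"].duplicated(), "specimen_id"].unique().tolist()
        raise ValueError(f"duplicate specimen ids in assignment file: {dupes}")
    series = check_assignment_series(pd.Series(df["group"].values, index=df["specimen_id"].values))
    unmatched: list[str] = []
    if known_ids is not None:
        known = set(known_ids)
        unmatched = [i for i in series.index if i not in known]
        series = series[series.index.isin(known)]
    return series, unmatched
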
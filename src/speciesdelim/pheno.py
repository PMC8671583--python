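"""Phenogroup discovery from continuous traits.

Pipeline: log-transformed complete-case traits -> robust PCA (projection
pursuit with a median-absolute-deviation spread measure, so gross outliers
do not steer the rotation) -> greedy forward selection of the score axes
that carry clustering signal -> Gaussian-mixture sweep over component
counts and covariance families.

The unsupervised sweep (the *Naive* model, "how many phenotypic species
does the data itself support?") is compared against models whose groups are
fixed a priori — the current taxonomy, or groups delimited by eye — on the
same BIC scale, yielding a ranked model table with ΔBIC against the best.
The component-count grid runs from 1 to ceil(n + n/2), where n is the
number of taxonomic species hypothesised for the clade.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .mixture import FAMILIES, MixtureFit, fit_from_labels, fit_gmm

__all__ = [
    "RotatedScores",
    "SweepResult",
    "ModelRanking",
    "robust_pca",
    "select_variables",
    "fit_naive",
    "fit_apriori",
    "compare_pheno_models",
    "k_grid_upper",
]


def k_grid_upper(n_taxa: int) -> int:
    """Top of the component grid: ceil(n + n/2)."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    return math.ceil(n_taxa + n_taxa / 2)


@dataclass
class RotatedScores:
    """Robust-PCA output: scores, orthonormal loadings, robust scales."""

    scores: np.ndarray  # (n, n_components)
    loadings: np.ndarray  # (d, n_components), columns orthonormal
    scales: np.ndarray  # robust (MAD-based) sd per component
    center: np.ndarray
    specimen_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def subset(self, components: Sequence[int]) -> np.ndarray:
        return self.scores[:, list(components)]


def _mad_scale(z: np.ndarray) -> float:
    return float(median_abs_deviation(z, scale="normal"))


def robust_pca(traits: np.ndarray, n_components: int | None = None) -> RotatedScores:
    """Sequential projection-pursuit PCA with a robust spread objective.

    Directions are found one at a time, each maximising the normal-consistent
    median absolute deviation of the projected (median-centred) data and each
    constrained orthogonal to its predecessors.  Candidate directions are the
    median-centred data points themselves (the classic projection-pursuit
    device): restricting the search to data directions tracks the leading
    eigenvector on clean elliptical samples while a continuous optimiser
    would chase the sampling noise of the MAD objective; gross outliers get
    a vote as candidates but cannot inflate the robust spread measure.

    ``traits`` must already be log-transformed and complete-case, with more
    rows than columns.
    """
    x = np.asarray(traits, dtype=float)
    if x.ndim != 2 or x.shape[0] <= x.shape[1]:
        raise ValueError("need a 2-D matrix with more specimens than traits")
    if np.isnan(x).any():
        raise ValueError("robust PCA requires complete cases; drop specimens with missing traits")
    n, d = x.shape
    spread = x.max(axis=0) - x.min(axis=0)
    if (spread == 0).any():
        const = [i for i in range(d) if spread[i] == 0]
        raise ValueError(f"constant trait column(s) at index {const}: no direction of variation")
    n_components = d if n_components is None else min(n_components, d)
    center = np.median(x, axis=0)
    xc = x - center

    loadings = np.zeros((d, n_components))
    basis = np.eye(d)  # orthonormal basis of the remaining subspace
    for comp in range(n_components):
        sub = xc @ basis  # coordinates in the remaining subspace
        m = basis.shape[1]
        if m == 1:
            v_sub = np.array([1.0])
        else:
            cands = sub[np.linalg.norm(sub, axis=1) > 0]
            cands = cands / np.linalg.norm(cands, axis=1, keepdims=True)
            proj = sub @ cands.T  # (n, n_candidates)
            scores_c = median_abs_deviation(proj, axis=0, scale="normal")
            v_sub = cands[int(np.argmax(scores_c))]
        v = basis @ v_sub
        loadings[:, comp] = v
        # deflate: orthonormal basis of the complement of v within `basis`
        if basis.shape[1] > 1:
            proj = basis - np.outer(v, v_sub)
            q, r = np.linalg.qr(proj)
            keep = np.abs(np.diag(r)) > 1e-12
            basis = q[:, keep][:, : basis.shape[1] - 1]

    scores = xc @ loadings
    scales = np.array([_mad_scale(scores[:, j]) for j in range(n_components)])
    return RotatedScores(scores=scores, loadings=loadings, scales=scales, center=center)


@dataclass
class SweepResult:
    """Best mixture fit from a (K, family) sweep plus the candidate table."""

    best: MixtureFit
    candidates: pd.DataFrame  # model, family, K, loglik, n_params, BIC, ICL, converged
    criterion: str = "bic"


def _sweep(
    x: np.ndarray,
    k_values: Iterable[int],
    families: Sequence[str],
    seed: int,
    criterion: str,
    model_name: str,
    n_restarts: int = 3,
) -> SweepResult:
    fits: list[MixtureFit] = []
    rows = []
    for k in k_values:
        for fam in families:
            try:
                fit = fit_gmm(x, k, fam, seed=seed + 1000 * k, n_restarts=n_restarts)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
            fits.append(fit)
            rows.append(
                {
                    "model": model_name,
                    "family": fam,
                    "K": k,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "BIC": fit.bic,
                    "ICL": fit.icl,
                    "converged": fit.converged,
                }
            )
    if not fits:
        raise RuntimeError(f"all mixture fits failed for model {model_name!r}")
    key = (lambda f: f.bic) if criterion == "bic" else (lambda f: f.icl)
    best = max(fits, key=key)
    return SweepResult(best=best, candidates=pd.DataFrame(rows), criterion=criterion)


def fit_naive(
    scores: RotatedScores | np.ndarray,
    n_taxa: int,
    families: Sequence[str] = FAMILIES,
    criterion: str = "bic",
    seed: int = 0,
    components: Sequence[int] | None = None,
) -> SweepResult:
    """The Naive model: unsupervised sweep over K = 1..ceil(n + n/2) x families.

    ``components`` restricts the score axes used (e.g. the forward-selected
    subset); default is all of them.
    """
    if criterion not in ("bic", "icl"):
        raise ValueError("criterion must be 'bic' or 'icl'")
    x = scores.scores if isinstance(scores, RotatedScores) else np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if components is not None:
        x = x[:, list(components)]
    kmax = k_grid_upper(n_taxa)
    return _sweep(x, range(1, kmax + 1), families, seed, criterion, "Naive")


def fit_apriori(
    scores: RotatedScores | np.ndarray,
    labels,
    families: Sequence[str] = FAMILIES,
    *,
    likelihood: str = "mixture",
    model_name: str = "Taxonomy",
    components: Sequence[int] | None = None,
) -> MixtureFit:
    """Score a fixed a-priori grouping (taxonomy, or groups drawn by eye).

    Parameters are the labelled-group MLEs (one M-step); the family is chosen
    by BIC across the candidate families.  By default the fit is scored with
    the observed-data mixture likelihood so it lives on the same surface as
    the Naive model; ``likelihood='classification'`` switches to the
    classification likelihood.
    """
    x = scores.scores if isinstance(scores, RotatedScores) else np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if components is not None:
        x = x[:, list(components)]
    labels = np.asarray(pd.Series(labels).astype(str))
    best: MixtureFit | None = None
    for fam in families:
        try:
            fit = fit_from_labels(x, labels, fam, likelihood=likelihood)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or fit.bic > best.bic:
            best = fit
    if best is None:
        raise RuntimeError(f"all a-priori fits failed for model {model_name!r}")
    return best


def select_variables(
    scores: RotatedScores | np.ndarray,
    k_grid: Sequence[int] | None = None,
    families: Sequence[str] = ("diagonal-varying", "full-varying"),
    seed: int = 0,
    max_k: int = 5,
) -> tuple[list[int], bool]:
    """Greedy forward selection of score axes that carry clustering signal.

    At each step, every unselected axis ``j`` is scored by its incremental
    clustering evidence relative to the already-selected set ``S``:

        evidence(j | S) = BIC_clust(S + [j]) - BIC_clust(S) - BIC_single(j)

    where ``BIC_clust`` is the best K>=2 clustered mixture over the family
    grid (and 0 for the empty set) and ``BIC_single`` the best
    single-component Gaussian on the axis alone — i.e. does adding the axis
    explain the data better than "clustering on S, plus j as unstructured
    noise"?  For the first axis this reduces to BIC(clustered) −
    BIC(single Gaussian) on that axis.  The axis with the largest positive
    evidence is added; selection stops when no axis improves.  If no axis
    ever shows positive evidence the single best-evidence axis is returned
    with a warning (never an empty set).  Returns
    ``(selected_indices_in_inclusion_order, warned)``.
    """
    x = scores.scores if isinstance(scores, RotatedScores) else np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    p = x.shape[1]
    if p < 1:
        raise ValueError("need at least one candidate component")
    ks = list(k_grid) if k_grid is not None else list(range(2, max_k + 1))
    if any(k < 2 for k in ks):
        raise ValueError("k_grid entries must be >= 2 (K=1 is the null)")
    fit_opts = dict(max_iter=300, tol=1e-7, n_restarts=2)

    def bic_single(cols: list[int]) -> float:
        return max(fit_gmm(x[:, cols], 1, fam, seed=seed).bic for fam in families)

    def bic_clust(cols: list[int]) -> float:
        if not cols:
            return 0.0
        alt = -np.inf
        for k in ks:
            for fam in families:
                try:
                    alt = max(alt, fit_gmm(x[:, cols], k, fam, seed=seed + 17 * k, **fit_opts).bic)
                except (RuntimeError, ValueError, np.linalg.LinAlgError):
                    continue
        return alt

    selected: list[int] = []
    best_single: tuple[float, int] | None = None
    while True:
        base = bic_clust(selected)
        gains = {}
        for j in range(p):
            if j in selected:
                continue
            gains[j] = bic_clust(selected + [j]) - base - bic_single([j])
        if not gains:
            break
        j_best = max(gains, key=lambda j: gains[j])
        if not selected:
            best_single = (gains[j_best], j_best)
        if gains[j_best] > 0:
            selected.append(j_best)
        else:
            break
    warned = False
    if not selected:
        assert best_single is not None
        warnings.warn(
            "no score axis showed positive clustering evidence; "
            f"returning the best single axis ({best_single[1]})",
            stacklevel=2,
        )
        selected = [best_single[1]]
        warned = True
    return selected, warned


@dataclass
class ModelRanking:
    """Ranked model table on the BIC (or ICL) scale; ΔBIC = best − model."""

    table: pd.DataFrame  # model, n_groups, criterion value, rank, delta

    def __getitem__(self, model: str) -> pd.Series:
        return self.table.set_index("model").loc[model]


def _dense_ranks(values: np.ndarray) -> np.ndarray:
    # larger value = better; exact ties share a rank (dense ranking)
    uniq = np.unique(values)[::-1]
    lookup = {v: r + 1 for r, v in enumerate(uniq)}
    return np.array([lookup[v] for v in values], dtype=int)


def compare_pheno_models(
    fits: dict[str, MixtureFit],
    criterion: str = "bic",
) -> ModelRanking:
    """Rank competing phenogroup models by BIC (larger is better).

    All fits must be on the same specimen set.  ΔBIC is the best model's
    criterion minus the model's (non-negative); exact ties share a rank.
    """
    if len(fits) < 1:
        raise ValueError("need at least one fit")
    if criterion not in ("bic", "icl"):
        raise ValueError("criterion must be 'bic' or 'icl'")
    hashes = {f.data_hash for f in fits.values()}
    n_obs = {f.n_obs for f in fits.values()}
    if len(hashes) > 1 or len(n_obs) > 1:
        raise ValueError("fits were computed on different specimen sets")
    names = list(fits)
    vals = np.array([getattr(fits[m], criterion) for m in names])
    ranks = _dense_ranks(vals)
    delta = vals.max() - vals
    table = pd.DataFrame(
        {
            "model": names,
            "n_groups": [fits[m].k for m in names],
            criterion.upper(): vals,
            "rank": ranks,
            f"delta_{criterion.upper()}": delta,
        }
    ).sort_values("rank", kind="stable").reset_index(drop=True)
    return ModelRanking(table=table)
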
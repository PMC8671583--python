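"""Gaussian finite mixture modelling with mclust-style covariance families.

The delimitation stages model a clade's specimens as a finite mixture of
multivariate normals: each component is a candidate species (a phenogroup on
robust-PCA scores, a genogroup on NMDS coordinates).  Fitting is plain EM;
model choice uses the Bayesian information criterion on the
larger-is-better scale

    BIC = 2 * loglik - n_params * log(N)

and the integrated complete-data likelihood criterion

    ICL = BIC - 2 * sum_i sum_k ( -z_ik * log z_ik )

which penalises BIC by the assignment entropy, so ICL <= BIC with equality
for hard (0/1) responsibilities.

Six covariance families are supported, spanning the spherical / diagonal /
full axis crossed with shared-versus-varying across components:

========================  =====================================
family                    covariance structure
========================  =====================================
``spherical-equal``       sigma^2 I, one sigma for all components
``spherical-varying``     sigma_k^2 I
``diagonal-equal``        diag(d), shared
``diagonal-varying``      diag(d_k)
``full-shared``           Sigma, shared
``full-varying``          Sigma_k
========================  =====================================
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = ["MixtureFit", "fit_gmm", "fit_from_labels", "FAMILIES", "n_mixture_params"]

FAMILIES: tuple[str, ...] = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-shared",
    "full-varying",
)

_MAX_RESTARTS = 5


def n_mixture_params(k: int, d: int, family: str) -> int:
    """Free parameters: K*d means, K-1 weights, plus the family's covariances."""
    base = k * d + (k - 1)
    if family == "spherical-equal":
        return base + 1
    if family == "spherical-varying":
        return base + k
    if family == "diagonal-equal":
        return base + d
    if family == "diagonal-varying":
        return base + k * d
    if family == "full-shared":
        return base + d * (d + 1) // 2
    if family == "full-varying":
        return base + k * d * (d + 1) // 2
    raise ValueError(f"unknown covariance family {family!r}; choose from {FAMILIES}")


@dataclass
class MixtureFit:
    """A fitted Gaussian mixture and its selection criteria."""

    k: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray  # (k, d, d), expanded regardless of family
    loglik: float
    n_params: int
    bic: float
    icl: float
    responsibilities: np.ndarray
    labels: np.ndarray  # argmax over responsibilities
    converged: bool
    seed: int | None
    n_obs: int
    loglik_trace: list[float] = field(default_factory=list)
    data_hash: str = ""

    @property
    def entropy(self) -> float:
        z = self.responsibilities
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(z > 0, z * np.log(z), 0.0)
        return float(-t.sum())


def _data_hash(x: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(x, dtype=float).tobytes()).hexdigest()[:16]


def _log_densities(x: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    n, d = x.shape
    out = np.empty((n, means.shape[0]))
    for k in range(means.shape[0]):
        chol = np.linalg.cholesky(covs[k])
        sol = solve_triangular(chol, (x - means[k]).T, lower=True, check_finite=False)
        maha = np.einsum("ij,ij->j", sol, sol)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, k] = -0.5 * (d * math.log(2 * math.pi) + logdet + maha)
    return out


def _m_step(
    x: np.ndarray,
    resp: np.ndarray,
    family: str,
    var_floor: float,
    min_count: float | None = None,
):
    n, d = x.shape
    nk = resp.sum(axis=0)
    # a component needs enough effective members to support a covariance;
    # otherwise the variance floor turns it into a degenerate likelihood
    # spike on one or two points that EM would happily keep
    threshold = (d + 1.0) if min_count is None else min_count
    if (nk < max(threshold, 1e-10)).any():
        raise _EmptyComponent
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    k = resp.shape[1]
    scatter = np.empty((k, d, d))
    for j in range(k):
        xc = x - means[j]
        scatter[j] = (resp[:, j, None] * xc).T @ xc
    if family == "full-varying":
        covs = scatter / nk[:, None, None]
    elif family == "full-shared":
        covs = np.repeat((scatter.sum(axis=0) / n)[None], k, axis=0)
    elif family == "diagonal-varying":
        covs = np.zeros((k, d, d))
        for j in range(k):
            np.fill_diagonal(covs[j], np.diag(scatter[j]) / nk[j])
    elif family == "diagonal-equal":
        shared = np.diag(np.diag(scatter.sum(axis=0)) / n)
        covs = np.repeat(shared[None], k, axis=0)
    elif family == "spherical-varying":
        covs = np.zeros((k, d, d))
        for j in range(k):
            np.fill_diagonal(covs[j], np.trace(scatter[j]) / (nk[j] * d))
    elif family == "spherical-equal":
        s2 = np.trace(scatter.sum(axis=0)) / (n * d)
        covs = np.repeat((s2 * np.eye(d))[None], k, axis=0)
    else:
        raise ValueError(f"unknown covariance family {family!r}; choose from {FAMILIES}")
    covs = _regularise(covs, var_floor)
    return weights, means, covs


def _regularise(covs: np.ndarray, var_floor: float) -> np.ndarray:
    # clip tiny/negative eigenvalues so every component stays PD
    for j in range(covs.shape[0]):
        covs[j] = (covs[j] + covs[j].T) / 2
        vals, vecs = np.linalg.eigh(covs[j])
        if vals.min() < var_floor:
            vals = np.maximum(vals, var_floor)
            covs[j] = (vecs * vals) @ vecs.T
    return covs


class _EmptyComponent(Exception):
    pass


def _e_step(x, weights, means, covs):
    log_dens = _log_densities(x, means, covs)
    weighted = log_dens + np.log(weights)
    norm = logsumexp(weighted, axis=1)
    resp = np.exp(weighted - norm[:, None])
    return resp, float(norm.sum())


def _criteria(loglik: float, n_params: int, resp: np.ndarray, n: int):
    bic = 2.0 * loglik - n_params * math.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(resp > 0, resp * np.log(resp), 0.0).sum()
    icl = bic - 2.0 * float(ent)
    return bic, icl


def fit_gmm(
    x: np.ndarray,
    k: int,
    family: str = "full-varying",
    seed: int | None = 0,
    *,
    max_iter: int = 1000,
    tol: float = 1e-8,
    n_restarts: int = _MAX_RESTARTS,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM.

    Each attempt starts from a fresh k-means++ hard assignment; up to
    ``n_restarts`` attempts are made and the best log-likelihood wins, with
    an early stop once two attempts agree on the optimum (replicating the
    best log-likelihood to relative 1e-6) — EM is deterministic given its
    start, so replication from an independent start is strong evidence the
    optimum is not a one-off local trap.  Attempts that empty a component
    are discarded.  Convergence within an attempt: relative log-likelihood
    change below ``tol`` (the per-iteration trace is retained on the fit).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more observations ({n}) than components ({k})")
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}; choose from {FAMILIES}")

    var_floor = 1e-6 * float(np.mean(np.var(x, axis=0)) + 1e-300)
    n_params = n_mixture_params(k, d, family)
    best: MixtureFit | None = None
    n_agree = 0
    rng = np.random.default_rng(seed)

    for attempt in range(max(1, n_restarts)):
        try:
            resp = _init_resp(x, k, rng)
            trace: list[float] = []
            loglik = -np.inf
            converged = False
            weights = means = covs = None
            for _ in range(max_iter):
                weights, means, covs = _m_step(x, resp, family, var_floor)
                resp, new_loglik = _e_step(x, weights, means, covs)
                trace.append(new_loglik)
                if np.isfinite(loglik):
                    denom = max(abs(loglik), 1.0)
                    if (new_loglik - loglik) / denom < tol:
                        loglik = new_loglik
                        converged = True
                        break
                loglik = new_loglik
        except _EmptyComponent:
            continue
        bic, icl = _criteria(loglik, n_params, resp, n)
        fit = MixtureFit(
            k=k,
            family=family,
            weights=weights,
            means=means,
            covariances=covs,
            loglik=loglik,
            n_params=n_params,
            bic=bic,
            icl=icl,
            responsibilities=resp,
            labels=resp.argmax(axis=1),
            converged=converged,
            seed=seed,
            n_obs=n,
            loglik_trace=trace,
            data_hash=_data_hash(x),
        )
        if best is None or fit.loglik > best.loglik + 1e-6 * max(abs(best.loglik), 1.0):
            best = fit
            n_agree = 1
        elif fit.loglik >= best.loglik - 1e-6 * max(abs(best.loglik), 1.0):
            n_agree += 1
        if k == 1 or (best.converged and n_agree >= 2):
            break

    if best is None:
        raise RuntimeError(
            f"EM failed for K={k}, family={family!r}: a component emptied in every restart"
        )
    return best


def _init_resp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    if k == 1:
        return np.ones((n, 1))
    centers, _ = kmeans_plusplus(x, n_clusters=k, random_state=int(rng.integers(2**31)))
    d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
    hard = d2.argmin(axis=1)
    if np.unique(hard).size < k:
        raise _EmptyComponent
    resp = np.zeros((n, k))
    resp[np.arange(n), hard] = 1.0
    return resp


def fit_from_labels(
    x: np.ndarray,
    labels: np.ndarray,
    family: str = "full-varying",
    *,
    likelihood: str = "mixture",
) -> MixtureFit:
    """Score an a-priori grouping as a Gaussian mixture.

    One M-step from the fixed labels gives per-group MLE parameters under the
    family (mixing proportions = group frequencies); the log-likelihood is then
    evaluated either as the observed-data mixture likelihood at those
    parameters (default, so labelled models are comparable with EM fits on the
    same surface) or as the classification likelihood
    ``sum_i log(w_{z_i} f_{z_i}(x_i))``.

    Singleton groups under a covariance-bearing family trigger variance-floor
    regularisation with a warning rather than failure.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels must match the number of observations")
    if likelihood not in ("mixture", "classification"):
        raise ValueError("likelihood must be 'mixture' or 'classification'")
    uniq, idx = np.unique(labels, return_inverse=True)
    k = uniq.size
    counts = np.bincount(idx, minlength=k)
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        warnings.warn(
            f"groups with a single specimen ({', '.join(small)}): "
            "variance-floor regularisation applied",
            stacklevel=2,
        )
    resp = np.zeros((n, k))
    resp[np.arange(n), idx] = 1.0
    var_floor = 1e-6 * float(np.mean(np.var(x, axis=0)) + 1e-300)
    # a-priori groups may legitimately be tiny; regularisation (with the
    # warning above) stands in for the member-count guard used during EM
    weights, means, covs = _m_step(x, resp, family, var_floor, min_count=0.0)
    post, mix_loglik = _e_step(x, weights, means, covs)
    if likelihood == "mixture":
        loglik = mix_loglik
        resp_out = post
    else:
        log_dens = _log_densities(x, means, covs)
        loglik = float((np.log(weights)[idx] + log_dens[np.arange(n), idx]).sum())
        resp_out = resp
    n_params = n_mixture_params(k, d, family)
    bic, icl = _criteria(loglik, n_params, resp_out, n)
    return MixtureFit(
        k=k,
        family=family,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik,
        n_params=n_params,
        bic=bic,
        icl=icl,
        responsibilities=resp_out,
        labels=idx,
        converged=True,
        seed=None,
        n_obs=n,
        loglik_trace=[loglik],
        data_hash=_data_hash(x),
    )
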
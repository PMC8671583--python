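"""Bayes-factor ranking of competing delimitation models.

Genomic delimitation models (genotypic clusters, cladogenesis/anagenesis
transition, reproductive isolation) are compared through their marginal
likelihoods, usually estimated externally by path sampling.  The Bayes
factor is reported on the 2·log_e scale,

    BF = 2 * (log ML_best - log ML_other),

with the Kass–Raftery reading: BF ≤ 2 "not worth more than a bare
mention", 2–6 positive, 6–10 strong, and BF > 10 decisive evidence for the
higher-ranked model.

Marginal likelihoods always arrive as numbers (a TSV of external runs, or
an internal fit's BIC explicitly labelled as a BIC approximation); nothing
here estimates a marginal likelihood itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["bayes_factor", "kass_raftery_label", "rank_models", "BFTable", "read_marginal_likelihoods"]


def bayes_factor(logml_best: float, logml_other: float) -> float:
    """2 x (log_e ML difference); antisymmetric in its arguments."""
    if not (math.isfinite(logml_best) and math.isfinite(logml_other)):
        raise ValueError("log marginal likelihoods must be finite")
    return 2.0 * (logml_best - logml_other)


def kass_raftery_label(bf: float) -> str:
    """Evidence reading of a 2·log_e Bayes factor."""
    if bf > 10:
        return "decisive"
    if bf > 6:
        return "strong"
    if bf > 2:
        return "positive"
    return "not worth more than a bare mention"


@dataclass
class BFTable:
    """Ranked marginal-likelihood table with Bayes factors vs the best model."""

    table: pd.DataFrame  # model, n_groups, logml, rank, BF, evidence

    def __getitem__(self, model: str) -> pd.Series:
        return self.table.set_index("model").loc[model]


def _dense_ranks_desc(values: np.ndarray) -> np.ndarray:
    uniq = np.unique(values)[::-1]
    lookup = {v: r + 1 for r, v in enumerate(uniq)}
    return np.array([lookup[v] for v in values], dtype=int)


def rank_models(models: dict[str, float] | pd.DataFrame, n_groups: dict[str, int] | None = None) -> BFTable:
    """Rank models by marginal likelihood and attach Bayes factors.

    ``models`` is either a mapping model name -> log_e marginal likelihood or
    a DataFrame with columns (model, n_groups, logml).  Exact ties in the
    marginal likelihood share a rank.  The best model's BF against itself is
    0 by convention.
    """
    if isinstance(models, pd.DataFrame):
        df = models.copy()
        required = {"model", "logml"}
        if not required.issubset(df.columns):
            raise ValueError(f"marginal-likelihood table needs columns {sorted(required)}")
        if "n_groups" not in df.columns:
            df["n_groups"] = np.nan
    else:
        df = pd.DataFrame(
            {
                "model": list(models),
                "n_groups": [
                    (n_groups or {}).get(m, np.nan) for m in models
                ],
                "logml": list(models.values()),
            }
        )
    if len(df) < 2:
        raise ValueError("need at least two models to rank")
    if df["model"].duplicated().any():
        dupes = df.loc[df["model"].duplicated(), "model"].tolist()
        raise ValueError(f"duplicate model names: {dupes}")
    logml = df["logml"].astype(float).to_numpy()
    if not np.isfinite(logml).all():
        raise ValueError("log marginal likelihoods must be finite")
    best = logml.max()
    df["rank"] = _dense_ranks_desc(logml)
    df["BF"] = np.array([bayes_factor(best, v) for v in logml])
    df["evidence"] = [
        "best" if bf == 0 else kass_raftery_label(bf) for bf in df["BF"]
    ]
    df = df.sort_values(["rank", "model"], kind="stable").reset_index(drop=True)
    return BFTable(table=df)


def read_marginal_likelihoods(path) -> pd.DataFrame:
    """Read a TSV of external marginal likelihoods (model, n_groups, logml)."""
    df = pd.read_csv(path, sep="\t")
    required = {"model", "logml"}
    if not required.issubset(df.columns):
        raise ValueError(f"marginal-likelihood table needs columns {sorted(required)}")
    return df
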
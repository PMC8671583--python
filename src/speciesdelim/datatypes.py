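"""Core containers shared across the pipeline.

Traits are stored on the raw measurement scale (strictly positive where
observed, NaN where missing); mixture modelling operates on the natural-log
scale, which :meth:`TraitMatrix.log_values` exposes.  Genotypes are diploid
biallelic minor-allele dosages coded 0/1/2 with -1 for missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "GenotypeMatrix",
    "SpeciesBox",
    "SpeciesBoxSet",
]

MISSING_GT = -1


@dataclass
class TraitMatrix:
    """Specimens x continuous traits, raw scale, NaN = missing."""

    values: np.ndarray
    specimen_ids: list[str]
    trait_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specimen_ids), len(self.trait_names)):
            raise ValueError(
                f"trait matrix shape {self.values.shape} does not match "
                f"{len(self.specimen_ids)} specimens x {len(self.trait_names)} traits"
            )
        observed = self.values[~np.isnan(self.values)]
        if observed.size and (observed <= 0).any():
            raise ValueError("trait values must be strictly positive (log scale required downstream)")

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def log_values(self) -> np.ndarray:
        """Natural-log view; NaN entries propagate."""
        with np.errstate(invalid="ignore"):
            return np.log(self.values)

    def complete_cases(self) -> "TraitMatrix":
        """Specimens with every trait observed (the mixture stage's input)."""
        keep = ~self.missing_mask.any(axis=1)
        return self.subset(np.flatnonzero(keep))

    def complete_case_ids(self) -> list[str]:
        keep = ~self.missing_mask.any(axis=1)
        return [s for s, k in zip(self.specimen_ids, keep) if k]

    def subset(self, indices: Sequence[int]) -> "TraitMatrix":
        idx = np.asarray(indices, dtype=int)
        return TraitMatrix(
            self.values[idx],
            [self.specimen_ids[i] for i in idx],
            list(self.trait_names),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.specimen_ids, columns=self.trait_names)


@dataclass
class GenotypeMatrix:
    """Specimens x biallelic loci; dosage codes {0,1,2}, -1 missing."""

    values: np.ndarray
    specimen_ids: list[str]
    locus_ids: list[str]
    monomorphic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.specimen_ids), len(self.locus_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.specimen_ids)} specimens x {len(self.locus_ids)} loci"
            )
        valid = np.isin(self.values, (MISSING_GT, 0, 1, 2))
        if not valid.all():
            bad = np.unique(self.values[~valid])
            raise ValueError(f"genotype codes must be in {{-1,0,1,2}}; found {bad.tolist()}")
        if self.monomorphic is None:
            self.monomorphic = self._find_monomorphic()

    def _find_monomorphic(self) -> np.ndarray:
        mono = np.zeros(self.n_loci, dtype=bool)
        for j in range(self.n_loci):
            col = self.values[:, j]
            obs = col[col != MISSING_GT]
            mono[j] = obs.size == 0 or (np.unique(obs).size == 1 and obs[0] in (0, 2))
        return mono

    @property
    def n_specimens(self) -> int:
        return len(self.specimen_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING_GT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.specimen_ids, columns=self.locus_ids)


@dataclass(frozen=True)
class SpeciesBox:
    """Axis-aligned hyperrectangle: a species description's trait ranges.

    With ten traits this is the "10-cube" of the matching-prediction
    analysis; intervals are closed (boundary values count as inside).
    """

    species: str
    trait_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.trait_names) == len(self.lower) == len(self.upper)):
            raise ValueError("trait_names, lower and upper must have equal length")
        for t, lo, hi in zip(self.trait_names, self.lower, self.upper):
            if lo > hi:
                raise ValueError(f"box {self.species!r}: min > max for trait {t!r}")

    @property
    def widths(self) -> np.ndarray:
        return np.asarray(self.upper) - np.asarray(self.lower)

    def volume(self, *, exclude_degenerate: bool = False) -> float:
        """Product of interval widths; optionally over positive-width dims only."""
        w = self.widths
        if exclude_degenerate:
            w = w[w > 0]
        return float(np.prod(w)) if w.size else 0.0


@dataclass
class SpeciesBoxSet:
    """Per-species boxes over a common trait set."""

    boxes: dict[str, SpeciesBox] = field(default_factory=dict)

    def __post_init__(self) -> None:
        traits = {b.trait_names for b in self.boxes.values()}
        if len(traits) > 1:
            raise ValueError("all boxes in a set must share one trait set")

    @property
    def species(self) -> list[str]:
        return list(self.boxes)

    @property
    def trait_names(self) -> tuple[str, ...]:
        if not self.boxes:
            return ()
        return next(iter(self.boxes.values())).trait_names

    def __getitem__(self, species: str) -> SpeciesBox:
        return self.boxes[species]

    def __contains__(self, species: str) -> bool:
        return species in self.boxes

    def __iter__(self):
        return iter(self.boxes.values())

    def __len__(self) -> int:
        return len(self.boxes)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": b.species, "trait": t, "min": lo, "max": hi}
            for b in self.boxes.values()
            for t, lo, hi in zip(b.trait_names, b.lower, b.upper)
        ]
        return pd.DataFrame(rows, columns=["taxon", "trait", "min", "max"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpeciesBoxSet":
        required = {"taxon", "trait", "min", "max"}
        if not required.issubset(df.columns):
            raise ValueError(f"range table needs columns {sorted(required)}")
        boxes = {}
        for taxon, grp in df.groupby("taxon", sort=False):
            boxes[str(taxon)] = SpeciesBox(
                species=str(taxon),
                trait_names=tuple(grp["trait"].astype(str)),
                lower=tuple(grp["min"].astype(float)),
                upper=tuple(grp["max"].astype(float)),
            )
        return cls(boxes)


def check_assignment_series(assignments: Mapping[str, object] | pd.Series) -> pd.Series:
    """Normalise an id -> group mapping into a string-valued Series."""
    s = pd.Series(dict(assignments)) if not isinstance(assignments, pd.Series) else assignments
    if s.index.has_duplicates:
        dupes = s.index[s.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate specimen ids in assignment: {dupes}")
    return s.astype(str)
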
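"""Geometric audit of taxonomic species descriptions.

A species description that tabulates a min and max for each of ten
quantitative traits implicitly claims the species occupies an axis-aligned
hyperrectangle (a "10-cube") in trait space.  This module treats those
claims as testable geometry: pairwise asymmetric overlap between boxes,
and a matching-prediction analysis asking whether measured specimens fall
inside their own species' box, any box, or none.

Geometry is computed on the raw measurement scale as tabulated in range
files.  Containment verdicts are invariant under any strictly increasing
per-trait transform; overlap *proportions* are scale-dependent and are
documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import SpeciesBox, SpeciesBoxSet, TraitMatrix

__all__ = ["asymmetric_overlap", "contains", "audit_clade", "overlap_matrix", "MatchReport"]


def asymmetric_overlap(a: SpeciesBox, b: SpeciesBox) -> float:
    """volume(a intersect b) / volume(a), exact, in [0, 1].

    Computed as the product over traits of the 1-D interval-overlap length
    divided by a's interval length.  A zero-width interval in ``a``
    contributes factor 1 if b's interval covers the point and 0 otherwise,
    and is excluded from the denominator volume, so point-valued ranges stay
    well defined.  A box degenerate in every dimension is rejected.
    """
    if a.trait_names != b.trait_names:
        raise ValueError(
            f"boxes {a.species!r} and {b.species!r} have different trait sets"
        )
    a_lo, a_hi = np.asarray(a.lower), np.asarray(a.upper)
    b_lo, b_hi = np.asarray(b.lower), np.asarray(b.upper)
    widths = a_hi - a_lo
    if (widths == 0).all():
        raise ValueError(
            f"box {a.species!r} is degenerate in every dimension; the "
            "zero-width policy needs at least one positive-width trait"
        )
    overlap = np.minimum(a_hi, b_hi) - np.maximum(a_lo, b_lo)
    ratio = 1.0
    for w, ov, lo, blo, bhi in zip(widths, overlap, a_lo, b_lo, b_hi):
        if w == 0:
            # point-valued range: in or out of b's closed interval
            if not (blo <= lo <= bhi):
                return 0.0
        else:
            if ov <= 0:
                return 0.0
            ratio *= min(ov, w) / w
    return float(ratio)


def contains(box: SpeciesBox, specimen: np.ndarray | dict) -> tuple[bool, list[str]]:
    """Is the specimen inside the closed box?  Returns (verdict, violated traits).

    One out-of-range trait suffices to place the specimen outside the whole
    hyperrectangle — the curse-of-dimensionality effect that drives the
    matching-prediction results.  Missing trait values are not allowed here;
    incomplete specimens are excluded upstream by :func:`audit_clade`.
    """
    if isinstance(specimen, dict):
        values = np.array([specimen[t] for t in box.trait_names], dtype=float)
    else:
        values = np.asarray(specimen, dtype=float)
        if values.shape != (len(box.trait_names),):
            raise ValueError(
                f"specimen has {values.shape} values; box {box.species!r} "
                f"has {len(box.trait_names)} traits"
            )
    if np.isnan(values).any():
        raise ValueError("specimen has missing traits; exclude incomplete specimens upstream")
    lo = np.asarray(box.lower)
    hi = np.asarray(box.upper)
    ok = (values >= lo) & (values <= hi)
    violated = [t for t, good in zip(box.trait_names, ok) if not good]
    return bool(ok.all()), violated


def overlap_matrix(boxes: SpeciesBoxSet) -> pd.DataFrame:
    """Ordered-pair overlap proportions; entry (A, B) = vol(A∩B)/vol(A)."""
    names = boxes.species
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a in names:
        for b in names:
            if a != b:
                mat.loc[a, b] = asymmetric_overlap(boxes[a], boxes[b])
    return mat


@dataclass
class MatchReport:
    """Matching-prediction verdicts plus the clade summary row."""

    per_specimen: pd.DataFrame  # specimen_id, taxon, inside_correct, inside_any, boxes_containing, violated_dims
    excluded_incomplete: list[str]
    overlaps: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def summary_row(self) -> pd.Series:
        return pd.Series(self.summary)


def audit_clade(traits: TraitMatrix, labels, boxes: SpeciesBoxSet) -> MatchReport:
    """Run the matching-prediction analysis for one clade.

    ``labels`` maps each specimen (in ``traits`` order or by id) to its
    taxonomic species; every labelled taxon must have a box.  Specimens with
    any missing trait are excluded from matching and reported separately.
    The summary mirrors the audit table layout: taxon and specimen counts,
    min/max pairwise overlap, percent of scored specimens inside any box and
    inside their own species' box.
    """
    labels = pd.Series(labels, index=traits.specimen_ids) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(traits.specimen_ids)
    unknown = sorted(set(labels.astype(str)) - set(boxes.species))
    if unknown:
        raise ValueError(f"no box for taxa: {unknown}")
    order = list(boxes.trait_names)
    missing_traits = [t for t in order if t not in traits.trait_names]
    if missing_traits:
        raise ValueError(f"trait matrix lacks box traits: {missing_traits}")
    col_idx = [traits.trait_names.index(t) for t in order]
    values = traits.values[:, col_idx]

    rows = []
    excluded = []
    for i, sid in enumerate(traits.specimen_ids):
        vec = values[i]
        if np.isnan(vec).any():
            excluded.append(sid)
            continue
        taxon = str(labels.iloc[i])
        inside = []
        violated_own: list[str] = []
        for box in boxes:
            ok, violated = contains(box, vec)
            if ok:
                inside.append(box.species)
            if box.species == taxon:
                violated_own = violated
        rows.append(
            {
                "specimen_id": sid,
                "taxon": taxon,
                "inside_correct": taxon in inside,
                "inside_any": bool(inside),
                "boxes_containing": inside,
                "violated_dims": violated_own,
            }
        )
    per_specimen = pd.DataFrame(
        rows,
        columns=["specimen_id", "taxon", "inside_correct", "inside_any", "boxes_containing", "violated_dims"],
    )
    ov = overlap_matrix(boxes)
    off_diag = ov.values[~np.eye(len(ov), dtype=bool)] if len(ov) > 1 else np.array([])
    n_scored = len(per_specimen)
    summary = {
        "n_taxa": len(boxes),
        "n_specimens_scored": n_scored,
        "n_specimens_incomplete": len(excluded),
        "min_overlap": float(off_diag.min()) if off_diag.size else np.nan,
        "max_overlap": float(off_diag.max()) if off_diag.size else np.nan,
        "pct_matching_any": 100.0 * per_specimen["inside_any"].mean() if n_scored else np.nan,
        "pct_matching_correct": 100.0 * per_specimen["inside_correct"].mean() if n_scored else np.nan,
    }
    return MatchReport(per_specimen=per_specimen, excluded_incomplete=excluded, overlaps=ov, summary=summary)
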
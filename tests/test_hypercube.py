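"""Hypercube geometry: exact overlap vs Monte-Carlo, containment, audits."""

import numpy as np
import pandas as pd
import pytest

from speciesdelim import SpeciesBox, SpeciesBoxSet, TraitMatrix
from speciesdelim.hypercube import asymmetric_overlap, audit_clade, contains, overlap_matrix


def _box(name, lo, hi):
    traits = tuple(f"t{i}" for i in range(len(lo)))
    return SpeciesBox(name, traits, tuple(map(float, lo)), tuple(map(float, hi)))


def _random_box_pair(rng, d=10):
    lo_a = rng.uniform(0, 5, d)
    a = _box("a", lo_a, lo_a + rng.uniform(0.5, 4, d))
    lo_b = rng.uniform(0, 5, d)
    b = _box("b", lo_b, lo_b + rng.uniform(0.5, 4, d))
    return a, b


def _mc_overlap(a, b, rng, n=100_000):
    """Monte-Carlo oracle: hit rate of uniform samples from a landing in b."""
    lo_a, hi_a = np.asarray(a.lower), np.asarray(a.upper)
    lo_b, hi_b = np.asarray(b.lower), np.asarray(b.upper)
    pts = rng.uniform(lo_a, hi_a, size=(n, len(lo_a)))
    return float(((pts >= lo_b) & (pts <= hi_b)).all(axis=1).mean())


def test_identity_overlap_is_one():
    a = _box("a", [0, 0], [2, 3])
    assert asymmetric_overlap(a, a) == 1.0


def test_closed_form_quarter_overlap():
    a = _box("a", [0, 0], [2, 2])
    b = _box("b", [1, 1], [3, 3])
    assert asymmetric_overlap(a, b) == pytest.approx(0.25)
    assert asymmetric_overlap(b, a) == pytest.approx(0.25)


def test_overlap_matches_monte_carlo(rng):
    """Exact overlaps agree with a 1e5-sample hit-rate oracle in 10-D."""
    for _ in range(20):
        a, b = _random_box_pair(rng)
        exact = asymmetric_overlap(a, b)
        assert exact == pytest.approx(_mc_overlap(a, b, rng), abs=0.01)


def test_overlap_symmetry_identity(rng):
    """overlap(a,b)*vol(a) == overlap(b,a)*vol(b) == vol(intersection)."""
    for _ in range(50):
        a, b = _random_box_pair(rng, d=4)
        lhs = asymmetric_overlap(a, b) * a.volume()
        rhs = asymmetric_overlap(b, a) * b.volume()
        assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-12)


def test_nested_box_overlap_is_one():
    inner = _box("a", [1, 1, 1], [2, 2, 2])
    outer = _box("b", [0, 0, 0], [3, 3, 3])
    assert asymmetric_overlap(inner, outer) == 1.0


def test_zero_width_dimension_policy():
    """Point-valued ranges: factor 1 if covered, 0 otherwise; excluded from volume."""
    point = _box("a", [1, 0], [1, 2])
    covering = _box("b", [0, 0], [2, 1])
    assert asymmetric_overlap(point, covering) == pytest.approx(0.5)
    missing = _box("c", [2, 0], [3, 2])
    assert asymmetric_overlap(point, missing) == 0.0
    fully_degenerate = _box("d", [1, 1], [1, 1])
    with pytest.raises(ValueError, match="degenerate"):
        asymmetric_overlap(fully_degenerate, covering)


def test_mismatched_traits_rejected():
    a = _box("a", [0], [1])
    b = SpeciesBox("b", ("other",), (0.0,), (1.0,))
    with pytest.raises(ValueError, match="trait sets"):
        asymmetric_overlap(a, b)


def test_contains_midpoint_and_single_violation():
    box = _box("a", [0] * 10, [1] * 10)
    inside, violated = contains(box, np.full(10, 0.5))
    assert inside and violated == []
    spec = np.full(10, 0.5)
    spec[3] = 1.5  # one trait out of ten is enough to fall outside
    inside, violated = contains(box, spec)
    assert not inside and violated == ["t3"]


def test_contains_matches_brute_force(rng):
    """Verdicts agree with an explicit per-dimension check on random inputs."""
    for _ in range(300):
        d = rng.integers(1, 8)
        lo = rng.uniform(-2, 2, d)
        hi = lo + rng.uniform(0, 3, d)
        box = _box("a", lo, hi)
        spec = rng.uniform(-3, 5, d)
        expected = all(lo[i] <= spec[i] <= hi[i] for i in range(d))
        inside, violated = contains(box, spec)
        assert inside == expected
        assert violated == [f"t{i}" for i in range(d) if not lo[i] <= spec[i] <= hi[i]]


def test_containment_invariant_under_log_transform(rng):
    """A strictly increasing per-trait transform can't change verdicts."""
    for _ in range(100):
        d = 5
        lo = rng.uniform(0.1, 2, d)
        hi = lo + rng.uniform(0.1, 2, d)
        spec = rng.uniform(0.05, 5, d)
        raw = contains(_box("a", lo, hi), spec)[0]
        logged = contains(_box("a", np.log(lo), np.log(hi)), np.log(spec))[0]
        assert raw == logged


def _audit_fixture():
    values = np.array([[0.5], [2.5], [1.5]])
    traits = TraitMatrix(values, ["s1", "s2", "s3"], ["t0"])
    labels = pd.Series(["A", "B", "A"], index=traits.specimen_ids)
    boxes = SpeciesBoxSet(
        {"A": _box("A", [0], [1]), "B": _box("B", [2], [3])}
    )
    return traits, labels, boxes


def test_audit_hand_enumerated_percentages():
    """{0.5:A in, 2.5:B in, 1.5:A out} -> 66.7% any, 66.7% correct."""
    traits, labels, boxes = _audit_fixture()
    report = audit_clade(traits, labels, boxes)
    assert report.summary["pct_matching_any"] == pytest.approx(66.7, abs=0.05)
    assert report.summary["pct_matching_correct"] == pytest.approx(66.7, abs=0.05)
    assert report.per_specimen["inside_correct"].tolist() == [True, True, False]
    # inside_correct implies inside_any, always
    df = report.per_specimen
    assert (df["inside_correct"] <= df["inside_any"]).all()


def test_audit_unknown_taxon_and_incomplete_specimens():
    traits, labels, boxes = _audit_fixture()
    with pytest.raises(ValueError, match="C"):
        audit_clade(traits, pd.Series(["A", "B", "C"], index=traits.specimen_ids), boxes)
    vals = traits.values.copy()
    vals[2, 0] = np.nan
    incomplete = TraitMatrix(vals, traits.specimen_ids, traits.trait_names)
    report = audit_clade(incomplete, labels, boxes)
    assert report.excluded_incomplete == ["s3"]
    assert report.summary["n_specimens_scored"] == 2
    assert report.summary["pct_matching_correct"] == pytest.approx(100.0)


def test_boxes_from_full_range_contain_all_members(small_clade):
    """Coverage (0,1) over all specimens -> every specimen inside its own box."""
    from speciesdelim import derive_taxonomic_ranges

    traits = small_clade.traits
    labels = small_clade.true_species
    boxes = derive_taxonomic_ranges(traits, labels, coverage=(0.0, 1.0))
    report = audit_clade(traits, labels, boxes)
    assert report.summary["pct_matching_correct"] == pytest.approx(100.0)


def test_narrow_coverage_boxes_reject_most_specimens(rng):
    """(0.25, 0.75) coverage per trait over 10 traits -> correct-match far below 50%."""
    from speciesdelim import derive_taxonomic_ranges, separated_scenario, simulate_traits

    scenario = separated_scenario(n_species=2, n_per_species=150, n_traits=10, seed=21)
    traits, _ = simulate_traits(scenario)
    labels = pd.Series(
        np.repeat(["A", "B"], 150), index=traits.specimen_ids
    )
    boxes = derive_taxonomic_ranges(traits, labels, coverage=(0.25, 0.75))
    report = audit_clade(traits, labels, boxes)
    # pairwise-independent product of per-trait coverage: ~0.5^10 of specimens inside
    assert report.summary["pct_matching_correct"] < 10.0


def test_overlap_matrix_diagonal_and_range():
    _, _, boxes = _audit_fixture()
    mat = overlap_matrix(boxes)
    assert (np.diag(mat.values) == 1.0).all()
    assert ((mat.values >= 0) & (mat.values <= 1)).all()
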
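"""Contingency construction, species-type classification, perfect matches."""

import itertools

import numpy as np
import pandas as pd
import pytest

from speciesdelim import (
    build_contingency,
    classify_cells,
    correspondence_summary,
    perfect_matches,
    propagate_unknowns,
)
from speciesdelim.integrate import pooled_good_species_percent


def _series(d):
    return pd.Series(d)


def test_full_overlap_no_unknowns():
    p = _series({"s1": "P1", "s2": "P1", "s3": "P2"})
    g = _series({"s1": "G1", "s2": "G1", "s3": "G2"})
    t = build_contingency(p, g)
    assert t.unknown_pheno_only == [] and t.unknown_geno_only == []
    assert t.n_assigned == 3


def test_partial_overlap_routes_to_unknowns():
    p = _series({"s1": "P1", "s2": "P1"})
    g = _series({"s1": "G1", "s3": "G2"})
    t = build_contingency(p, g)
    assert t.unknown_pheno_only == ["s2"]
    assert t.unknown_geno_only == ["s3"]
    assert t.n_assigned == 1
    assert t.n_assigned + t.n_unknown == 3


def test_disjoint_sets_all_unknown():
    t = build_contingency(_series({"a": "P1"}), _series({"b": "G1"}))
    assert t.n_assigned == 0
    assert t.unknown_pheno_only == ["a"] and t.unknown_geno_only == ["b"]


def test_orphan_specimen_rejected():
    with pytest.raises(ValueError, match="neither"):
        build_contingency(_series({"a": "P1"}), _series({"a": "G1"}), all_ids=["a", "zz"])


def test_diagonal_table_is_all_good():
    p = _series({"s1": "P1", "s2": "P2"})
    g = _series({"s1": "G1", "s2": "G2"})
    cells = classify_cells(build_contingency(p, g))
    assert sorted(c.species_type for c in cells) == ["good", "good"]


def test_phenogroup_spanning_two_genogroups_is_phenotypic_cryptic():
    p = _series({"s1": "P2", "s2": "P2"})
    g = _series({"s1": "G1", "s2": "G2"})
    cells = classify_cells(build_contingency(p, g))
    assert [c.species_type for c in cells] == ["phenotypic_cryptic", "phenotypic_cryptic"]


def _brute_force_type(occ, i, j):
    row = occ[i].sum()
    col = occ[:, j].sum()
    if row == 1 and col == 1:
        return "good"
    if row > 1 and col == 1:
        return "phenotypic_cryptic"
    if row == 1 and col > 1:
        return "genetic_cryptic"
    return "complex"


def test_all_512_occupancy_patterns_match_bruteforce():
    """Every 3x3 occupancy pattern classifies per the row/column-count rule."""
    for bits in itertools.product([0, 1], repeat=9):
        occ = np.array(bits).reshape(3, 3)
        if occ.sum() == 0:
            continue
        p, g = {}, {}
        sid = 0
        for i in range(3):
            for j in range(3):
                if occ[i, j]:
                    p[f"s{sid}"] = f"P{i}"
                    g[f"s{sid}"] = f"G{j}"
                    sid += 1
        cells = classify_cells(build_contingency(_series(p), _series(g)))
        got = {(c.phenogroup, c.genogroup): c.species_type for c in cells}
        for i in range(3):
            for j in range(3):
                if occ[i, j]:
                    assert got[(f"P{i}", f"G{j}")] == _brute_force_type(occ.astype(bool), i, j)


def test_classification_invariant_to_permutation(rng):
    p = _series({f"s{i}": f"P{rng.integers(3)}" for i in range(30)})
    g = _series({f"s{i}": f"G{rng.integers(3)}" for i in range(30)})
    base = {(c.phenogroup, c.genogroup): c.species_type
            for c in classify_cells(build_contingency(p, g))}
    relabel = {"P0": "P2", "P1": "P0", "P2": "P1"}
    permuted = {(relabel[k[0]], k[1]): v for k, v in base.items()}
    cells2 = classify_cells(build_contingency(p.map(relabel), g))
    assert {(c.phenogroup, c.genogroup): c.species_type for c in cells2} == permuted


def test_perfect_matches_identity_and_split():
    part = _series({"a": "x", "b": "x", "c": "y"})
    assert perfect_matches(part, part) == 2
    other = _series({"a": "p", "b": "q", "c": "r"})  # x split across p, q
    assert perfect_matches(part, other) == 1  # only y<->r survives
    assert perfect_matches(other, part) == 1  # symmetric


def test_perfect_matches_against_bruteforce(rng):
    """Random partitions of 12 specimens vs an all-pairs set-equality oracle."""
    ids = [f"s{i}" for i in range(12)]
    for _ in range(30):
        a = _series({i: f"A{rng.integers(4)}" for i in ids})
        b = _series({i: f"B{rng.integers(4)}" for i in ids})
        blocks_a = [frozenset(a.index[a == v]) for v in a.unique()]
        blocks_b = [frozenset(b.index[b == v]) for v in b.unique()]
        oracle = sum(1 for x in blocks_a for y in blocks_b if x == y)
        assert perfect_matches(a, b) == oracle


def test_perfect_matches_empty_intersection_rejected():
    with pytest.raises(ValueError, match="share no specimens"):
        perfect_matches(_series({"a": "x"}), _series({"b": "y"}))


def test_pooled_good_species_percentage():
    """Published per-clade species and joint-match counts pool to 17%."""
    species = [2, 2, 6, 2, 7, 10]
    joint = [1, 0, 1, 1, 0, 2]
    pct = pooled_good_species_percent(species, joint)
    assert round(pct) == 17


def test_correspondence_full_concordance():
    part = _series({"a": "x", "b": "x", "c": "y", "d": "z"})
    rep = correspondence_summary(part, part, part)
    assert rep.n_taxa == rep.n_phenogroups == rep.n_genogroups == 3
    assert rep.match_pheno == rep.match_geno == rep.match_joint == 3


def test_correspondence_joint_partition():
    """Joint matches use the (phenogroup, genogroup) product partition."""
    taxa = _series({"a": "x", "b": "x", "c": "y"})
    pheno = _series({"a": "P1", "b": "P1", "c": "P1"})  # lumps everything
    geno = _series({"a": "G1", "b": "G1", "c": "G2"})
    rep = correspondence_summary(taxa, pheno, geno)
    assert rep.match_pheno == 0
    assert rep.match_geno == 2
    assert rep.match_joint == 2  # product partition splits P1 into P1|G1, P1|G2


def _geo(points):
    return pd.DataFrame(points, columns=["lat", "lon"])


def test_propagate_unknown_unanimous_neighbourhood():
    p = _series({"a": "P2", "b": "P2", "u": "P9"}).drop("u")
    g = _series({"a": "G1", "b": "G1", "u": "G1"})
    t = build_contingency(p, g)
    geo = _geo({"a": [0.0, 0.0], "b": [0.1, 0.0], "u": [0.05, 0.0]}).T
    geo = pd.DataFrame({"lat": [0.0, 0.1, 0.05], "lon": [0.0, 0.0, 0.0]}, index=["a", "b", "u"])
    out = propagate_unknowns(t, geo, k=2)
    row = out.set_index("specimen_id").loc["u"]
    assert row["missing_side"] == "phenogroup"
    assert row["provisional"] == "P2" and not row["tie"]


def test_propagate_unknown_tie_flagged():
    p = _series({"a": "P1", "b": "P2"})
    g = _series({"a": "G1", "b": "G1", "u": "G1"})
    t = build_contingency(p, g)
    geo = pd.DataFrame({"lat": [0.0, 0.2, 0.1], "lon": [0.0, 0.0, 0.0]}, index=["a", "b", "u"])
    out = propagate_unknowns(t, geo, k=2)
    row = out.set_index("specimen_id").loc["u"]
    assert row["provisional"] is None and row["tie"]


def test_propagate_k_truncates_to_assigned_set():
    p = _series({"a": "P1", "b": "P1"})
    g = _series({"a": "G1", "b": "G1", "u": "G1"})
    t = build_contingency(p, g)
    geo = pd.DataFrame({"lat": [0.0, 0.2, 0.1], "lon": [0.0, 0.0, 0.0]}, index=["a", "b", "u"])
    out = propagate_unknowns(t, geo, k=50)
    assert out.set_index("specimen_id").loc["u", "provisional"] == "P1"


def test_cell_counts_plus_unknowns_total(rng):
    ids = [f"s{i}" for i in range(40)]
    p = _series({i: f"P{rng.integers(3)}" for i in ids[:30]})
    g = _series({i: f"G{rng.integers(3)}" for i in ids[10:]})
    t = build_contingency(p, g)
    assert t.n_assigned + t.n_unknown == 40
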
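"""Synthetic-clade generator: distributional checks against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from speciesdelim import (
    CladeScenario,
    derive_taxonomic_ranges,
    separated_scenario,
    simulate_clade,
    simulate_genotypes,
    simulate_traits,
)


def _wc_fst(geno, pops):
    """Weir–Cockerham theta over loci: the independent Fst oracle."""
    a_sum = b_sum = c_sum = 0.0
    pops = np.asarray(pops)
    r = len(np.unique(pops))
    for j in range(geno.shape[1]):
        col = geno[:, j].astype(float)
        ok = col >= 0
        ns, ps, hs = [], [], []
        for p in np.unique(pops):
            sel = ok & (pops == p)
            n_i = sel.sum()
            if n_i == 0:
                break
            ns.append(n_i)
            ps.append(col[sel].mean() / 2.0)
            hs.append((col[sel] == 1).mean())
        if len(ns) < r:
            continue
        ns, ps, hs = map(np.asarray, (ns, ps, hs))
        nbar = ns.mean()
        if nbar <= 1:
            continue
        C = ns.sum()
        nc = (C - (ns**2).sum() / C) / (r - 1)
        pbar = (ns * ps).sum() / C
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * hs).sum() / C
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    return a_sum / (a_sum + b_sum + c_sum)


def _one_group_scenario(n, n_traits=4, seed=0, **kw):
    return CladeScenario(
        n_species=1,
        specimens_per_species=[n],
        trait_means=np.linspace(0.5, 2.0, n_traits),
        trait_covariances=np.diag(np.full(n_traits, 0.09)),
        seed=seed,
        **kw,
    )


def test_trait_means_match_specified_distribution():
    """Monte-Carlo check: per-trait log-scale sample mean within 3 SE of spec."""
    sc = _one_group_scenario(1000, seed=42)
    traits, labels = simulate_traits(sc)
    logs = traits.log_values()
    se = 0.3 / np.sqrt(1000)
    assert (np.abs(logs.mean(axis=0) - sc.trait_means[0]) < 3 * se).all()
    assert set(labels) == {"P1"}


def test_trait_covariance_converges_with_n():
    """Frobenius distance of the sample covariance shrinks as n grows."""
    cov = np.array([[0.09, 0.03], [0.03, 0.09]])
    errs = []
    for n in (50, 500, 5000):
        sc = CladeScenario(1, [n], np.array([[1.0, 1.0]]), cov, seed=7)
        traits, _ = simulate_traits(sc)
        sample = np.cov(traits.log_values().T)
        errs.append(np.linalg.norm(sample - cov))
    assert errs[0] > errs[1] > errs[2]


def test_missingness_rates():
    sc0 = _one_group_scenario(200, missing_rate_traits=0.0)
    assert not simulate_traits(sc0)[0].missing_mask.any()
    sc = _one_group_scenario(500, missing_rate_traits=0.5, seed=3)
    rate = simulate_traits(sc)[0].missing_mask.mean()
    assert rate == pytest.approx(0.5, abs=0.03)


def test_seed_determinism():
    """Identical scenario + seed => bit-identical clade."""
    sc = separated_scenario(n_species=2, n_per_species=15, n_traits=3, n_loci=50,
                            missing_rate_traits=0.1, missing_rate_snps=0.25, seed=9)
    a = simulate_clade(sc)
    b = simulate_clade(sc)
    np.testing.assert_array_equal(a.traits.values, b.traits.values)
    np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
    assert a.taxonomy_labels.equals(b.taxonomy_labels)
    assert a.boxes.to_frame().equals(b.boxes.to_frame())


def test_non_pd_covariance_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError, match="phenogroup 0"):
        CladeScenario(1, [10], np.zeros((1, 2)), bad[None])


def test_parameter_validation():
    with pytest.raises(ValueError, match="divergence"):
        separated_scenario(divergence=1.0)
    with pytest.raises(ValueError, match="missing_rate_snps"):
        separated_scenario(missing_rate_snps=1.5)


def test_fst_zero_under_panmixia():
    """divergence=0: the WC estimate over 2000 loci is ~0."""
    sc = CladeScenario(
        2, [50, 50], np.zeros((2, 2)), np.repeat(np.eye(2)[None] * 0.04, 2, 0),
        n_loci=2000, divergence=0.0, genogroup_of_species=[0, 0], seed=13,
    )
    geno, demes = simulate_genotypes(sc)
    halves = np.repeat([0, 1], 50)  # arbitrary split of one panmictic deme
    assert abs(_wc_fst(geno.values, halves)) < 0.02
    assert set(demes) == {"G1"}


def test_fst_matches_divergence_parameter():
    """divergence=0.3, 2 demes, 2000 loci -> WC estimate within 0.05."""
    sc = CladeScenario(
        2, [50, 50], np.zeros((2, 2)), np.repeat(np.eye(2)[None] * 0.04, 2, 0),
        n_loci=2000, divergence=0.3, seed=17,
    )
    geno, demes = simulate_genotypes(sc)
    pops = (demes.values == "G2").astype(int)
    assert _wc_fst(geno.values, pops) == pytest.approx(0.3, abs=0.05)


def test_hardy_weinberg_at_zero_divergence():
    """Within-deme genotype frequencies obey HWE: chi-square rejects ~nominally."""
    sc = CladeScenario(
        1, [300], np.zeros((1, 2)), np.eye(2)[None] * 0.04,
        n_loci=400, divergence=0.0, seed=23,
    )
    geno, _ = simulate_genotypes(sc)
    pvals = []
    for j in range(geno.n_loci):
        col = geno.values[:, j]
        p = col.mean() / 2
        if p < 0.1 or p > 0.9:
            continue
        n = len(col)
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        obs = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()])
        stat = ((obs - exp) ** 2 / exp).sum()
        pvals.append(1 - stats.chi2.cdf(stat, df=1))
    reject = np.mean(np.asarray(pvals) < 0.05)
    assert 0.0 <= reject < 0.12  # ~nominal 5% rate


def test_full_missingness_refused_downstream():
    from speciesdelim import shared_allele_distance

    sc = separated_scenario(n_species=2, n_per_species=5, n_traits=2, n_loci=20,
                            missing_rate_snps=1.0, seed=3)
    geno, _ = simulate_genotypes(sc)
    assert geno.missing_mask.all()
    with pytest.raises(ValueError, match="no non-missing locus"):
        shared_allele_distance(geno)


def test_monomorphic_loci_flagged():
    sc = CladeScenario(1, [8], np.zeros((1, 2)), np.eye(2)[None] * 0.04,
                       n_loci=300, divergence=0.0, seed=2)
    geno, _ = simulate_genotypes(sc)
    j = int(np.flatnonzero(geno.monomorphic)[0]) if geno.monomorphic.any() else None
    if j is not None:
        obs = geno.values[:, j]
        assert np.unique(obs[obs >= 0]).size == 1


def test_range_boxes_quantiles_and_minimums():
    """Default coverage is the observed min/max; held-out tails fall outside."""
    rng = np.random.default_rng(4)
    vals = np.array([[1.0], [2.0], [3.0]])
    from speciesdelim import TraitMatrix

    tm = TraitMatrix(vals, ["a", "b", "c"], ["t"])
    boxes = derive_taxonomic_ranges(tm, pd.Series(["x", "x", "x"], index=["a", "b", "c"]))
    assert boxes["x"].lower == (1.0,) and boxes["x"].upper == (3.0,)

    n = 400
    tm2 = TraitMatrix(np.exp(rng.normal(size=(n, 1))), [f"s{i}" for i in range(n)], ["t"])
    labels = pd.Series(["x"] * n, index=tm2.specimen_ids)
    described = tm2.specimen_ids[: n // 2]
    boxes = derive_taxonomic_ranges(tm2, labels, coverage=(0.1, 0.9), described_subset=described)
    held = tm2.values[n // 2 :, 0]
    lo, hi = boxes["x"].lower[0], boxes["x"].upper[0]
    outside = ((held < lo) | (held > hi)).mean()
    # binomial expectation: ~20% of held-out specimens in the excluded tails
    assert outside == pytest.approx(0.2, abs=0.08)


def test_range_boxes_need_two_specimens():
    from speciesdelim import TraitMatrix

    tm = TraitMatrix(np.array([[1.0], [2.0]]), ["a", "b"], ["t"])
    labels = pd.Series(["x", "y"], index=["a", "b"])
    with pytest.raises(ValueError, match="'x'"):
        derive_taxonomic_ranges(tm, labels)


def test_label_noise_creates_discordance():
    sc = separated_scenario(n_species=3, n_per_species=40, n_traits=3, n_loci=30,
                            label_noise=0.2, seed=31)
    clade = simulate_clade(sc)
    frac = (clade.taxonomy_labels.values != clade.true_species.values).mean()
    assert frac == pytest.approx(0.2, abs=0.08)


def test_scenario_yaml_round_trip(tmp_path):
    sc = separated_scenario(n_species=2, n_per_species=10, n_traits=3, n_loci=40, seed=5)
    path = tmp_path / "scenario.yaml"
    sc.to_yaml(path)
    back = CladeScenario.from_yaml(path)
    np.testing.assert_allclose(back.trait_means, sc.trait_means)
    assert back.seed == sc.seed and back.n_loci == sc.n_loci
    a = simulate_clade(sc)
    b = simulate_clade(back)
    np.testing.assert_array_equal(a.genotypes.values, b.genotypes.values)
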
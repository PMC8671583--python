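"""Discover phenogroups with Gaussian mixtures and rank them against taxonomy.

Simulates a three-species clade with 20% mislabelled specimens, rotates the
log traits with robust PCA, forward-selects the informative axes, sweeps
mixtures (the Naive model) and compares against the noisy taxonomy scored as
an a-priori model.
"""

import pandas as pd

from speciesdelim import (
    compare_pheno_models,
    fit_apriori,
    fit_naive,
    robust_pca,
    select_variables,
    separated_scenario,
    simulate_clade,
)

scenario = separated_scenario(n_species=3, n_per_species=50, n_traits=10,
                              label_noise=0.2, seed=8)
clade = simulate_clade(scenario)

complete = clade.traits.complete_cases()
rotated = robust_pca(complete.log_values())
selected, _ = select_variables(rotated, seed=8)
print(f"forward selection kept score axes {selected} of {rotated.n_components}")

naive = fit_naive(rotated, n_taxa=3, seed=8, components=selected)
taxonomy = fit_apriori(rotated, clade.taxonomy_labels.loc[complete.specimen_ids],
                       components=selected)
ranking = compare_pheno_models({"Naive": naive.best, "Taxonomy": taxonomy})
print(ranking.table.to_string(index=False))
print()
print(f"Naive model found K={naive.best.k} phenogroups ({naive.best.family}).")
print("The positive delta-BIC of the Taxonomy row is the cost of the 20%")
print("mislabelled specimens: the data-driven mixture explains the trait")
print("variation better than the noisy a-priori classification.")
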
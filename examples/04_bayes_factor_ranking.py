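"""Rank genomic delimitation models by Bayes factors.

Marginal likelihoods (log_e) come from external Bayesian runs — here the
published four-model comparison for one clade — and are ranked on the
2·log_e Bayes-factor scale with the Kass–Raftery evidence reading.
"""

from speciesdelim import rank_models

marginal_likelihoods = {
    "AC": -4588.693,   # cladogenesis/anagenesis transition
    "GC": -5381.361,   # genotypic clusters
    "RIa": -5601.058,  # reproductive isolation (one deme assignment)
    "RIb": -6085.998,  # reproductive isolation (another assignment)
}
n_groups = {"AC": 10, "GC": 6, "RIa": 3, "RIb": 2}
table = rank_models(marginal_likelihoods, n_groups).table
print(table.to_string(index=False))
print()
print("BF is twice the log marginal-likelihood gap to the best model; every")
print("value above 10 is decisive evidence, so the top-ranked model wins")
print("outright for this clade.")
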
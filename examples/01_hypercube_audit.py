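"""Audit taxonomic trait ranges as geometry.

Builds monograph-style min/max range boxes from a "described" half of a
simulated two-species clade, then asks whether the remaining specimens fall
inside their own species' 10-trait hyperrectangle.
"""

import numpy as np

from speciesdelim import audit_clade, derive_taxonomic_ranges, separated_scenario, simulate_clade

scenario = separated_scenario(n_species=2, n_per_species=60, n_traits=10, seed=4)
clade = simulate_clade(scenario)

# ranges from a described subsample at inner-quantile coverage: each trait
# interval covers only the central 50% of described specimens
described = clade.traits.specimen_ids[::2]
boxes = derive_taxonomic_ranges(
    clade.traits, clade.true_species, coverage=(0.25, 0.75), described_subset=described
)
report = audit_clade(clade.traits, clade.true_species, boxes)
s = report.summary

print(f"taxa: {s['n_taxa']}, specimens scored: {s['n_specimens_scored']}")
print(f"pairwise box overlap: min {s['min_overlap']:.2f}, max {s['max_overlap']:.2f}")
print(f"% specimens inside any box:     {s['pct_matching_any']:.1f}")
print(f"% specimens inside correct box: {s['pct_matching_correct']:.1f}")
print()
print("Even with every single trait covering the central half of described")
print("variation, almost no specimen satisfies all ten intervals at once —")
print("the curse of dimensionality that undermines fixed-range descriptions.")
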
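"""Simulate a single-cell DNA-seq sample from a random clonal tree.

Builds an 8-mutation clonal tree, draws clone prevalences, samples 3,000
cells, and overlays the platform's error processes (1% false positives,
5.8% allele dropout, 5% missing entries).
"""

import numpy as np

import clonalevo as ce

tree = ce.simulate_tree(8, seed=11)
fractions = ce.simulate_clone_fractions(
    tree, dirichlet_alpha=10.0, wt_fraction=0.05, seed=12
)[0]
true_gt, nodes = ce.genotypes_from_tree(
    tree, fractions, n_cells=3000, seed=13, return_assignments=True
)
observed = ce.add_observation_noise(
    true_gt, fpr=0.01, fnr=0.058, missing_rate=0.05, seed=14
)

print("clonal tree (newick):", tree.to_newick())
print("clone prevalences    :", np.round(fractions, 3))
print("cells per node       :", np.bincount(nodes, minlength=tree.n_nodes))
print("observed mutant calls:", (observed.codes == 1).mean().round(4))
print("observed missing     :", (observed.codes == 3).mean().round(4))

# The true matrix is a perfect phylogeny (nested/disjoint mutant cell sets);
# the observed matrix is what the platform would report for these cells and
# is the input every downstream stage consumes.
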
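"""Single-threshold GMYC delimitation on a clock tree.

Simulates coalescent gene trees for six species, fits the mixed
Yule-coalescent model (threshold scanned over node heights), tests it
against the single-regime null by likelihood ratio, and reports ensemble
node support with entities merged at the 0.9 cutoff.
"""

from specdelim.gmyc import gmyc_fit, gmyc_support, tree_from_string
from specdelim.simulate import calibrated_species_tree, simulate_gene_trees

species_newick, ages = calibrated_species_tree(6, 0.3, seed=13, min_split_my=1.5)
gene_trees = simulate_gene_trees(species_newick, theta=0.008, n_per_species=5,
                                 seed=99, markers={"COI": 0.25})
tree = tree_from_string(gene_trees["COI"][0])

fit = gmyc_fit(tree)
print(f"tips: {tree.n_tips}   true species: 6")
print(f"lnL null {fit.lnL_null:.2f}  lnL mixed {fit.lnL_alt:.2f}  "
      f"LR {fit.LR:.2f}  p {fit.p_value:.2g}")
print(f"threshold {fit.threshold_time:.3f} My before present -> "
      f"{fit.n_entities} GMYC entities")

support = gmyc_support(tree, cutoff=0.9)
high = sum(1 for s in support.support.values() if s >= 0.9)
print(f"{high} nodes with ensemble support >= 0.9; entities after "
      f"support-merging: {support.n_entities}")
print("a significant LR plus stable entities across model variants is the "
      "GMYC evidence for distinct species")
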
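"""Test one gene for differential expression with the two-part hurdle model.

The hurdle splits a gene's signal into detection (is it expressed in the
cell?) and level (how highly, given detection, on log(x+1)). With a random
intercept per individual both parts respect that cells from one donor are
correlated; without it, every cell is wrongly treated as an independent
replicate.
"""

import numpy as np

import hierpower as hp

model = hp.default_truth_model()
design = hp.SimulationDesign(n_genes=2, frac_de=0.5, n_per_group=10,
                             cells_per_individual=100, fold_change=1.5, seed=21)
ds = hp.simulate_binary(design, model)

for i in range(ds.n_genes):
    label = "effect gene (FC 1.5)" if ds.de_flags[i] else "null gene"
    print(f"\n{ds.gene_ids[i]} — {label}")
    for re_ in (True, False):
        fit = hp.fit_hurdle(ds.counts[i], ds.phenotype_of_cell,
                            ds.individual_of_cell, random_effects=re_)
        kind = "mixed (random intercept)" if re_ else "naive (cells independent)"
        print(f"  {kind:<28} chi2 = {fit.stat_combined:7.2f} "
              f"on {fit.df_combined} df  p = {fit.p_value:.3g}")
    stat, p = hp.pseudobulk_test(ds.counts[i], ds.phenotype_of_cell,
                                 ds.individual_of_cell)
    print(f"  {'pseudo-bulk (Welch t)':<28} t    = {stat:7.2f}           p = {p:.3g}")

print(
    "\nThe naive fit piles up pseudo-replication: its statistic dwarfs the"
    "\nmixed one even for the null gene. The mixed hurdle and the pseudo-bulk"
    "\ntest judge evidence at the level of the 20 donors, which is what the"
    "\nstudy actually sampled."
)
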
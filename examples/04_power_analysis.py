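"""Estimate power and type-1 error for a planned two-group study.

Monte-Carlo: simulate genes under the design, test each one, count
rejections at alpha = 0.05. Run once with the effect (power) and once with
the effect nullified (type-1 error). Scaled to 150 genes per estimate so
the example finishes in about a minute; use 500+ for production estimates.
"""

import hierpower as hp

model = hp.default_truth_model()
design = hp.SimulationDesign(n_per_group=10, cells_per_individual=50,
                             fold_change=1.5, seed=31)

print("design: 10 individuals/group, 50 cells each, fold change 1.5, alpha 0.05\n")
print(f"{'method':<14}{'power':>8}{'type1':>8}   (mc se ~0.03 at 150 genes)")
for method in ("hurdle_mixed", "hurdle_naive", "pseudobulk"):
    pw = hp.estimate_power(design, model, method=method, n_genes=150, seed=31)
    t1 = hp.estimate_type1(design, model, method=method, n_genes=150, seed=31)
    print(f"{method:<14}{pw.power:>8.3f}{t1.type1:>8.3f}")

print(
    "\nThe naive hurdle's power is not comparable to the others: its type-1"
    "\nerror is far above the nominal 0.05, so its rejections are unreliable."
    "\nThe mixed hurdle and pseudo-bulk hold their level; their power numbers"
    "\nare the ones to plan a study with."
)
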
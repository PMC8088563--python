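"""Fit the generative model to pilot single-cell expression data.

Builds a synthetic pilot matrix (the role normally played by a real pilot
dataset), runs the estimation pipeline — gene pruning, grand-mean
resampling, variance decomposition, dispersion and dropout fits — and
prints the fitted hyper-parameters next to the known truth.
"""

import hierpower as hp

truth = hp.default_truth_model()
spec = hp.FixtureSpec(n_genes=1500, n_individuals=10, cells_per_individual=90, seed=1)
pilot = hp.generate_pilot(spec)
print(f"pilot data: {pilot.n_genes} genes x {pilot.n_cells} cells "
      f"from {len(pilot.individuals)} individuals")

model = hp.estimate_model(pilot, prune_threshold=0.25, n_resamples=1000, seed=1)

print(f"\n{'parameter':<22}{'fitted':>14}{'truth':>14}")
rows = [
    ("gamma shape", model.grand_mean_gamma[0], truth.grand_mean_gamma[0]),
    ("gamma rate", model.grand_mean_gamma[1], truth.grand_mean_gamma[1]),
    ("f1 intercept", model.f1[0], truth.f1[0]),
    ("f1 slope", model.f1[1], truth.f1[1]),
    ("f2 intercept", model.f2[0], truth.f2[0]),
    ("f2 slope", model.f2[1], truth.f2[1]),
    ("dropout gamma shape", model.dropout_gamma[0], truth.dropout_gamma[0]),
    ("dropout gamma rate", model.dropout_gamma[1], truth.dropout_gamma[1]),
]
for name, est, tru in rows:
    print(f"{name:<22}{est:>14.4f}{tru:>14.4f}")

print(
    "\nThe gamma row describes the spread of per-gene mean expression (TPM);"
    "\nf1 maps a gene's mean to its between-individual variance; f2 maps the"
    "\nmean to the negative-binomial size (within-individual dispersion); the"
    "\ndropout gamma describes per-gene zero-inflation. At 1,500 genes the"
    "\nfits typically land within ~10-15% of truth; a 5,000-gene pilot"
    "\ntightens them to a few percent."
)
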
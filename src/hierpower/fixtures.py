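"""Synthetic pilot data with known ground truth.

These generators stand in for a real pilot expression matrix (a few
thousand genes over ~10 donors with on the order of a hundred cells each)
so the estimation pipeline can be exercised end to end without any
download. The default truth model is a fixture constant chosen to mimic
the qualitative structure of published single-cell TPM data — right-skewed
gene means, inter-individual variance growing with the mean, negative-
binomial overdispersion shrinking slowly with the mean, dropout rates
centered a little below one half — in a regime where the pipeline's moment
estimators are informative at pilot scale (see docs/methods.md). It is not
a claim about any particular dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SimulationModel
from .simulate import simulate_pilot


def default_truth_model() -> SimulationModel:
    """The fixture's known hyper-parameters (see module docstring)."""
    return SimulationModel(
        grand_mean_gamma=(1.2, 0.012),   # mean 100 TPM, strongly right-skewed
        f1=(10.0, 2.0),                  # inter-individual variance trend
        f2=(4.0, 2.0),                   # NB size = 4 + 2 log(mean)
        dropout_gamma=(8.0, 17.78),      # dropout rates, mean ~0.45
        provenance={"source": "synthetic fixture truth"},
    )


@dataclass
class FixtureSpec:
    """Recipe for a pilot-like matrix with known truth.

    ``correlated_blocks`` lists sizes of gene blocks to append: each block
    is one freshly simulated base gene plus rank-preserving noisy copies,
    giving within-block Spearman correlations near 1 to exercise pruning.
    """

    truth: SimulationModel = field(default_factory=default_truth_model)
    n_genes: int = 2000
    n_individuals: int = 10
    cells_per_individual: int = 90
    correlated_blocks: Optional[Sequence[int]] = None
    seed: int = 0


def generate_pilot(spec: FixtureSpec) -> ExpressionMatrix:
    """Simulate an effect-free pilot matrix under the spec's truth model.

    Correlated blocks (if any) are appended after the ``n_genes``
    independent genes, with ids ``block{b}_gene{k}``.
    """
    blocks = list(spec.correlated_blocks or [])
    n_base = spec.n_genes + len(blocks)
    ds = simulate_pilot(
        spec.truth, n_base, spec.n_individuals, spec.cells_per_individual, seed=spec.seed
    )
    values = ds.counts[: spec.n_genes]
    gene_ids = [f"gene{i}" for i in range(spec.n_genes)]

    if blocks:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(8)[7])
        rows = [values]
        for b, size in enumerate(blocks):
            base = ds.counts[spec.n_genes + b]
            block = [base]
            # uniform noise below the unit count spacing never reorders
            # distinct values, so Spearman with the base stays near 1
            for _ in range(size - 1):
                block.append(base + rng.uniform(0.0, 0.4, size=base.size))
            rows.append(np.vstack(block))
            gene_ids.extend(f"block{b}_gene{k}" for k in range(size))
        values = np.vstack(rows)

    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=list(ds.cell_ids),
        individual_of_cell=ds.individual_of_cell,
    )


def tiny_worked_fixture() -> tuple[ExpressionMatrix, dict]:
    """A hand-sized matrix whose parameter estimates are known exactly.

    5 genes x 9 cells over 3 individuals (A, B, C; 3 cells each). The
    expected values below were computed by hand from the definitions
    (zero fractions; sample variance of per-individual non-zero means;
    size = m^2/(v - m) on non-zero within-individual moments; plain
    grand-mean expectation = average of per-individual cell means) and are
    never recomputed by package code.
    """
    values = np.array(
        [
            [2, 4, 0, 6, 6, 6, 0, 0, 3],      # g1
            [10, 20, 30, 10, 10, 40, 20, 20, 20],  # g2
            [0, 0, 0, 0, 0, 0, 0, 0, 5],      # g3
            [1, 1, 1, 3, 3, 3, 5, 5, 5],      # g4
            [4, 8, 0, 6, 2, 4, 9, 0, 3],      # g5
        ],
        dtype=float,
    )
    x = ExpressionMatrix(
        values=values,
        gene_ids=["g1", "g2", "g3", "g4", "g5"],
        cell_ids=["a1", "a2", "a3", "b1", "b2", "b3", "c1", "c2", "c3"],
        individual_of_cell=np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3, dtype=object),
    )
    expected = {
        "dropout_rate": {"g1": 3 / 9, "g2": 0.0, "g3": 8 / 9, "g4": 0.0, "g5": 2 / 9},
        # sample variance (ddof=1) of per-individual means of non-zero values:
        # g1: (3, 6, 3) -> 3.0; g2: (20, 20, 20) -> 0; g3: < 2 individuals -> NaN;
        # g4: (1, 3, 5) -> 4.0; g5: (6, 4, 6) -> 4/3
        "inter_indiv_var": {"g1": 3.0, "g2": 0.0, "g3": float("nan"),
                            "g4": 4.0, "g5": 4 / 3},
        # NB size from non-zero within moments where var > mean:
        # (g2,A): m=20, v=100 -> 400/80 = 5; (g2,B): m=20, v=300 -> 400/280 = 10/7
        # (g5,A): m=6, v=8 -> 36/2 = 18;     (g5,C): m=6, v=18 -> 36/12 = 3
        "dispersion": {("g2", "A"): 5.0, ("g2", "B"): 10 / 7,
                       ("g5", "A"): 18.0, ("g5", "C"): 3.0},
        # Poisson-like (var <= mean) pairs, capped and flagged:
        # (g1,A): m=3, v=2; (g5,B): m=4, v=4
        "capped": {("g1", "A"), ("g5", "B")},
        # exact expectation of the all-cells resampled grand mean
        # = average of per-individual plain means
        "grand_mean_plain": {"g1": 3.0, "g2": 20.0, "g3": 5 / 9, "g4": 3.0, "g5": 4.0},
    }
    return x, expected


def truth_as_frame(model: SimulationModel) -> pd.DataFrame:
    """Truth hyper-parameters as a tidy one-row frame (for provenance files)."""
    (gs, gr), (f1a, f1b), (f2a, f2b), (ds_, dr) = (
        model.grand_mean_gamma, model.f1, model.f2, model.dropout_gamma,
    )
    return pd.DataFrame(
        [{"gamma_shape": gs, "gamma_rate": gr, "f1_intercept": f1a, "f1_slope": f1b,
          "f2_a": f2a, "f2_b": f2b, "dropout_shape": ds_, "dropout_rate": dr}]
    )
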
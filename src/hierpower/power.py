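"""Monte-Carlo power and type-1 error estimation.

Genes are simulated independently (one single-gene dataset per Monte-Carlo
draw, matching the independence of genes in the simulator), tested with the
chosen method, and the rejection proportion at the nominal alpha is
reported with its binomial standard error. Type-1 error uses the identical
code path on the nullified design (fold change 1 / rho 0), so power at a
null design equals type-1 error by construction. No multiple-testing
correction is applied: power is per-test at fixed alpha.

Reproducibility: the root seed is split into one substream per gene via
``numpy.random.SeedSequence.spawn``, so grids and partial re-runs are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import SimulationDesign, SimulationModel
from .hurdle import fit_hurdle, pseudobulk_test
from .simulate import simulate_binary, simulate_continuous

__all__ = ["PowerEstimate", "estimate_power", "estimate_type1", "power_grid", "METHODS"]

METHODS = ("hurdle_mixed", "hurdle_naive", "pseudobulk")


@dataclass
class PowerEstimate:
    """Rejection proportion among simulated genes, with Monte-Carlo error."""

    rejection_rate: float
    kind: str                 # 'power' (effect genes) or 'type1' (null genes)
    mc_se: float
    n_genes_tested: int
    n_rejected: int
    n_failed_fits: int
    method: str
    alpha: float
    test_type: str
    design: SimulationDesign
    seed: int
    p_values: Optional[np.ndarray] = None

    @property
    def power(self) -> Optional[float]:
        return self.rejection_rate if self.kind == "power" else None

    @property
    def type1(self) -> Optional[float]:
        return self.rejection_rate if self.kind == "type1" else None


def _gene_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def _test_one(values, predictor, individual_of_cell, method, test_type):
    """Returns (p_value, fit_ok)."""
    if method in ("hurdle_mixed", "hurdle_naive"):
        fit = fit_hurdle(
            values, predictor, individual_of_cell,
            random_effects=(method == "hurdle_mixed"), test_type=test_type,
        )
        return fit.p_value, fit.ok
    if method == "pseudobulk":
        try:
            _, p = pseudobulk_test(values, predictor, individual_of_cell)
            return p, True
        except ValueError:
            return 1.0, False
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def _rejection_loop(design, model, method, alpha, n_genes, seed, test_type, keep_pvalues):
    simulate = simulate_binary if design.kind == "binary" else simulate_continuous
    seeds = _gene_seeds(seed, n_genes)
    n_rej = 0
    n_failed = 0
    pvals = np.empty(n_genes)
    for g, s in enumerate(seeds):
        d = replace(design, n_genes=1, frac_de=1.0, seed=s)
        ds = simulate(d, model)
        p, ok = _test_one(ds.counts[0], ds.phenotype_of_cell, ds.individual_of_cell,
                          method, test_type)
        pvals[g] = p
        if not ok:
            n_failed += 1       # never counted as a rejection (conservative)
        elif p <= alpha:
            n_rej += 1
    rate = n_rej / n_genes
    mc_se = float(np.sqrt(rate * (1.0 - rate) / n_genes))
    return rate, mc_se, n_rej, n_failed, (pvals if keep_pvalues else None)


def estimate_power(
    design: SimulationDesign,
    model: SimulationModel,
    method: str = "hurdle_mixed",
    alpha: float = 0.05,
    n_genes: int = 500,
    seed: Optional[int] = None,
    test_type: str = "lrt",
    keep_pvalues: bool = False,
) -> PowerEstimate:
    """Monte-Carlo power: rejection proportion among genes carrying the effect.

    Each gene is simulated under the design's effect (fold change or rho),
    tested at the given alpha, and counted as rejected when its p-value is
    at most alpha. Fits that fail to converge are tallied separately and
    never counted as rejections.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    seed = design.seed if seed is None else seed
    rate, mc_se, n_rej, n_failed, pvals = _rejection_loop(
        design, model, method, alpha, n_genes, seed, test_type, keep_pvalues
    )
    return PowerEstimate(
        rejection_rate=rate, kind="power", mc_se=mc_se,
        n_genes_tested=n_genes, n_rejected=n_rej, n_failed_fits=n_failed,
        method=method, alpha=alpha, test_type=test_type, design=design, seed=seed,
        p_values=pvals,
    )


def estimate_type1(
    design: SimulationDesign,
    model: SimulationModel,
    method: str = "hurdle_mixed",
    alpha: float = 0.05,
    n_genes: int = 500,
    seed: Optional[int] = None,
    test_type: str = "lrt",
    keep_pvalues: bool = False,
) -> PowerEstimate:
    """Type-1 error: the power loop run on the nullified design (FC 1 / rho 0)."""
    est = estimate_power(
        design.nullified(), model, method=method, alpha=alpha, n_genes=n_genes,
        seed=seed if seed is not None else design.seed,
        test_type=test_type, keep_pvalues=keep_pvalues,
    )
    est.kind = "type1"
    return est


def power_grid(
    designs: Sequence[SimulationDesign],
    model: SimulationModel,
    methods: Sequence[str] = ("hurdle_mixed",),
    alpha: float = 0.05,
    n_genes: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-product power evaluation; one tidy row per design x method.

    Every cell of the grid gets its own seed derived from the root seed, so
    the whole table is reproducible and individual cells can be re-run.
    """
    if not designs or not methods:
        raise ValueError("designs and methods must be non-empty")
    cell_seeds = _gene_seeds(seed, len(designs) * len(methods))
    rows = []
    k = 0
    for design in designs:
        for method in methods:
            est = estimate_power(design, model, method=method, alpha=alpha,
                                 n_genes=n_genes, seed=cell_seeds[k])
            rows.append(
                {
                    "kind": design.kind,
                    "effect": design.fold_change if design.kind == "binary" else design.rho,
                    "n_individuals": (
                        design.n_per_group if design.kind == "binary" else design.n_individuals
                    ),
                    "cells_per_individual": design.cells_per_individual,
                    "cell_count_mode": design.cell_count_mode,
                    "method": method,
                    "alpha": alpha,
                    "power": est.rejection_rate,
                    "mc_se": est.mc_se,
                    "n_genes": n_genes,
                    "n_failed_fits": est.n_failed_fits,
                    "seed": cell_seeds[k],
                }
            )
            k += 1
    return pd.DataFrame(rows)
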
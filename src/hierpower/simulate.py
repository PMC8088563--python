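"""Hierarchical single-cell count simulation.

For each gene i a grand mean mu_i is drawn from the fitted gamma; each
individual j receives mu_ij = mu_i + Normal(0, f1(mu_i)), truncated below
at 0; each cell k of individual j draws Y_ijk ~ NB(mean mu_ij,
size f2(group mean)); finally a per-gene dropout probability drawn from the
bounded gamma zeroes cells independently. Binary effects multiply the grand
mean by the fold change in one group (direction Bernoulli(0.5)); continuous
effects couple the individual-level mean deviations to a simulated
phenotype with correlation rho.

Determinism: every dataset is generated from one root seed split into named
per-stage streams via ``numpy.random.SeedSequence.spawn`` in a fixed order
(grand means, effect directions / phenotype coupling, individual means,
cell counts, NB draws, dropout rates, dropout mask), so the same seed gives
a bit-identical dataset.
"""

from __future__ import annotations

import numpy as np

from .containers import SimulationDesign, SimulationModel, SimulatedDataset

__all__ = [
    "draw_cells_per_individual",
    "draw_grand_means",
    "apply_effect_binary",
    "draw_individual_means",
    "draw_counts",
    "draw_dropout_rates",
    "apply_dropout",
    "simulate_binary",
    "simulate_continuous",
    "simulate_pilot",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def draw_cells_per_individual(mode: str, expected: int, n_individuals: int, seed) -> np.ndarray:
    """Realized cell counts per individual under one of three regimes.

    fixed: every individual has exactly ``expected`` cells. poisson:
    iid Poisson(expected) — slight imbalance. negbin: iid NB with mean
    ``expected`` and size 1 — strong imbalance. Zero draws are redrawn so
    every individual contributes at least one cell.
    """
    if expected < 1:
        raise ValueError("expected cells per individual must be >= 1")
    rng = _rng(seed)
    if mode == "fixed":
        return np.full(n_individuals, int(expected), dtype=int)
    if mode == "poisson":
        draw = lambda n: rng.poisson(expected, size=n)  # noqa: E731
    elif mode == "negbin":
        # NB(mean, size=1): p = size / (size + mean)
        draw = lambda n: rng.negative_binomial(1, 1.0 / (1.0 + expected), size=n)  # noqa: E731
    else:
        raise ValueError(f"unknown cell_count_mode {mode!r}")
    counts = draw(n_individuals)
    while np.any(counts == 0):
        zero = counts == 0
        counts[zero] = draw(int(zero.sum()))
    return counts.astype(int)


def draw_grand_means(model: SimulationModel, n_genes: int, seed) -> np.ndarray:
    """iid gamma(shape, rate) grand means, one per gene."""
    shape, rate = model.grand_mean_gamma
    return _rng(seed).gamma(shape, scale=1.0 / rate, size=n_genes)


def apply_effect_binary(
    mu: np.ndarray, fold_change: float, de_flags: np.ndarray, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Spike DE genes by the fold change in one group, direction Bernoulli(0.5).

    Returns (group_means, applied_effect) where group_means has shape
    (2, n_genes) and applied_effect is +fold_change when group 1 is spiked,
    -fold_change when group 0 is spiked, and 0 for null genes.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be > 0")
    mu = np.asarray(mu, dtype=float)
    de_flags = np.asarray(de_flags, dtype=bool)
    rng = _rng(seed)
    group_means = np.vstack([mu, mu]).astype(float)
    applied = np.zeros(mu.size)
    de_idx = np.flatnonzero(de_flags)
    spike_group1 = rng.random(de_idx.size) < 0.5
    g1 = de_idx[spike_group1]
    g0 = de_idx[~spike_group1]
    group_means[1, g1] = mu[g1] * fold_change
    group_means[0, g0] = mu[g0] * fold_change
    applied[g1] = fold_change
    applied[g0] = -fold_change
    return group_means, applied


def draw_individual_means(mu_i: float, model: SimulationModel, n_individuals: int, seed) -> np.ndarray:
    """mu_ij = mu_i + Normal(0, f1(mu_i)), truncated below at 0."""
    var = float(model.inter_individual_variance(mu_i))
    devs = _rng(seed).normal(0.0, np.sqrt(var), size=n_individuals) if var > 0 else np.zeros(n_individuals)
    return np.maximum(mu_i + devs, 0.0)


def draw_counts(mu_ij, size_i, n_cells: int, seed) -> np.ndarray:
    """iid NB(mean mu_ij, size size_i) read counts via the gamma-Poisson mixture.

    ``mu_ij`` and ``size_i`` may be scalars or broadcastable arrays; a mean
    of 0 yields all-zero draws. Large sizes behave as Poisson.
    """
    rng = _rng(seed)
    mu = np.asarray(mu_ij, dtype=float)
    size = np.asarray(size_i, dtype=float)
    if np.any(mu < 0):
        raise ValueError("NB means must be non-negative")
    if np.any(size <= 0):
        raise ValueError("NB sizes must be positive")
    shape = np.broadcast_shapes(mu.shape, size.shape)
    if shape == ():
        shape = (n_cells,)
    mu_b = np.broadcast_to(mu, shape)
    size_b = np.broadcast_to(size, shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mu_b > 0, mu_b / size_b, 0.0)
    lam = rng.gamma(size_b, scale=scale)
    return rng.poisson(lam)


def draw_dropout_rates(model: SimulationModel, n_genes: int, seed) -> np.ndarray:
    """Per-gene dropout probabilities from the bounded gamma (rejection into [0,1])."""
    shape, rate = model.dropout_gamma
    rng = _rng(seed)
    rates = rng.gamma(shape, scale=1.0 / rate, size=n_genes)
    while np.any(rates > 1.0):
        bad = rates > 1.0
        rates[bad] = rng.gamma(shape, scale=1.0 / rate, size=int(bad.sum()))
    return rates


def apply_dropout(counts: np.ndarray, dropout_rate, seed) -> np.ndarray:
    """Independently zero each cell value with its gene's dropout probability."""
    counts = np.asarray(counts)
    rates = np.asarray(dropout_rate, dtype=float)
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("dropout rates must lie in [0, 1]")
    if counts.ndim == 2 and rates.ndim == 1:
        rates = rates[:, None]
    mask = _rng(seed).random(counts.shape) < rates
    out = counts.copy()
    out[mask] = 0
    return out


# ---------------------------------------------------------------------------
# full dataset composition

def _choose_de(n_genes: int, frac_de: float, rng: np.random.Generator) -> np.ndarray:
    n_de = int(round(frac_de * n_genes))
    flags = np.zeros(n_genes, dtype=bool)
    flags[rng.permutation(n_genes)[:n_de]] = True
    return flags


def _cells_layout(individual_ids, cells_per_ind):
    individual_of_cell = np.repeat(np.asarray(individual_ids, dtype=object), cells_per_ind)
    cell_ids = [f"cell{k}" for k in range(individual_of_cell.size)]
    return individual_of_cell, cell_ids


def _generate_counts(group_of_ind, mu_groups, sizes_groups, cells_per_ind, model,
                     rng_ind, rng_nb):
    """Counts + realized individual means given per-(group, gene) means/sizes.

    group_of_ind maps each individual to a column of mu_groups (shape
    n_groups x n_genes).
    """
    n_ind = len(group_of_ind)
    n_genes = mu_groups.shape[1]
    # individual means: genes x individuals
    mu_ij = np.empty((n_genes, n_ind))
    for j, grp in enumerate(group_of_ind):
        mu_g = mu_groups[grp]
        var = model.inter_individual_variance(mu_g)
        devs = rng_ind.normal(0.0, 1.0, size=n_genes) * np.sqrt(var)
        mu_ij[:, j] = np.maximum(mu_g + devs, 0.0)
    # expand to cells
    cell_of_ind = np.repeat(np.arange(n_ind), cells_per_ind)
    mu_cells = mu_ij[:, cell_of_ind]
    size_cells = np.empty_like(mu_cells)
    for grp in np.unique(group_of_ind):
        cols = np.isin(cell_of_ind, np.flatnonzero(np.asarray(group_of_ind) == grp))
        size_cells[:, cols] = sizes_groups[grp][:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mu_cells > 0, mu_cells / size_cells, 0.0)
    lam = rng_nb.gamma(size_cells, scale=scale)
    return rng_nb.poisson(lam).astype(float), mu_ij


def _stage_rngs(seed: int, n: int = 7) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_binary(design: SimulationDesign, model: SimulationModel) -> SimulatedDataset:
    """Two-group hierarchical dataset with fold-change effects on DE genes."""
    if design.kind != "binary":
        raise ValueError("design is not binary (no fold_change)")
    (rng_grand, rng_effect, rng_ind, rng_cells, rng_nb,
     rng_drop_rates, rng_drop_mask) = _stage_rngs(design.seed)

    n_pg = design.n_per_group
    mu = draw_grand_means(model, design.n_genes, rng_grand)
    de_flags = _choose_de(design.n_genes, design.frac_de, rng_effect)
    group_means, applied = apply_effect_binary(mu, design.fold_change, de_flags, rng_effect)
    # inter-individual variance and dispersion are evaluated at the group's
    # (possibly spiked) mean
    sizes = np.vstack([model.nb_size(group_means[0]), model.nb_size(group_means[1])])

    group_of_ind = [0] * n_pg + [1] * n_pg
    individual_ids = [f"ind{j}" for j in range(2 * n_pg)]
    cells_per_ind = draw_cells_per_individual(
        design.cell_count_mode, design.cells_per_individual, 2 * n_pg, rng_cells
    )
    counts, mu_ij = _generate_counts(group_of_ind, group_means, sizes, cells_per_ind,
                                     model, rng_ind, rng_nb)
    rates = draw_dropout_rates(model, design.n_genes, rng_drop_rates)
    counts = apply_dropout(counts, rates, rng_drop_mask)

    individual_of_cell, cell_ids = _cells_layout(individual_ids, cells_per_ind)
    return SimulatedDataset(
        counts=counts,
        gene_ids=[f"gene{i}" for i in range(design.n_genes)],
        cell_ids=cell_ids,
        individual_of_cell=individual_of_cell,
        individual_ids=individual_ids,
        phenotype_of_individual=np.asarray(group_of_ind, dtype=float),
        de_flags=de_flags,
        applied_effect=applied,
        kind="binary",
        design=design,
        grand_means=mu,
        individual_means=mu_ij,
    )


def simulate_continuous(design: SimulationDesign, model: SimulationModel) -> SimulatedDataset:
    """Hierarchical dataset whose DE genes correlate with a continuous phenotype.

    The phenotype P_j ~ Normal(mean, sd^2) per individual. For a DE gene the
    individual mean deviation is sqrt(f1(mu_i)) * (rho * s_j +
    sqrt(1-rho^2) * e_j) with s_j the standardized phenotype and e_j iid
    standard normal, so the individual-level mean/phenotype correlation
    targets rho. Null genes have zero phenotype loading. Cell-level
    correlation is attenuated by within-individual NB noise.
    """
    if design.kind != "continuous":
        raise ValueError("design is not continuous (no rho)")
    (rng_grand, rng_effect, rng_ind, rng_cells, rng_nb,
     rng_drop_rates, rng_drop_mask) = _stage_rngs(design.seed)

    n_ind = design.n_individuals
    rho = float(design.rho)
    mu = draw_grand_means(model, design.n_genes, rng_grand)
    de_flags = _choose_de(design.n_genes, design.frac_de, rng_effect)
    applied = np.where(de_flags, rho, 0.0)

    pheno = rng_effect.normal(design.phenotype_mean, design.phenotype_sd, size=n_ind)
    s = (pheno - design.phenotype_mean) / design.phenotype_sd

    var = model.inter_individual_variance(mu)
    sd = np.sqrt(var)
    e = rng_ind.normal(0.0, 1.0, size=(design.n_genes, n_ind))
    load = np.where(de_flags, rho, 0.0)[:, None]
    devs = sd[:, None] * (load * s[None, :] + np.sqrt(1.0 - load**2) * e)
    mu_ij = np.maximum(mu[:, None] + devs, 0.0)

    individual_ids = [f"ind{j}" for j in range(n_ind)]
    cells_per_ind = draw_cells_per_individual(
        design.cell_count_mode, design.cells_per_individual, n_ind, rng_cells
    )
    cell_of_ind = np.repeat(np.arange(n_ind), cells_per_ind)
    mu_cells = mu_ij[:, cell_of_ind]
    size_cells = model.nb_size(mu)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(mu_cells > 0, mu_cells / size_cells, 0.0)
    lam = rng_nb.gamma(np.broadcast_to(size_cells, mu_cells.shape), scale=scale)
    counts = rng_nb.poisson(lam).astype(float)

    rates = draw_dropout_rates(model, design.n_genes, rng_drop_rates)
    counts = apply_dropout(counts, rates, rng_drop_mask)

    individual_of_cell, cell_ids = _cells_layout(individual_ids, cells_per_ind)
    return SimulatedDataset(
        counts=counts,
        gene_ids=[f"gene{i}" for i in range(design.n_genes)],
        cell_ids=cell_ids,
        individual_of_cell=individual_of_cell,
        individual_ids=individual_ids,
        phenotype_of_individual=pheno,
        de_flags=de_flags,
        applied_effect=applied,
        kind="continuous",
        design=design,
        grand_means=mu,
        individual_means=mu_ij,
    )


def simulate_pilot(
    model: SimulationModel,
    n_genes: int,
    n_individuals: int,
    cells_per_individual: int,
    seed: int = 0,
    cell_count_mode: str = "fixed",
) -> SimulatedDataset:
    """Effect-free hierarchical data: pilot-like input for estimation."""
    (rng_grand, _rng_effect, rng_ind, rng_cells, rng_nb,
     rng_drop_rates, rng_drop_mask) = _stage_rngs(seed)
    mu = draw_grand_means(model, n_genes, rng_grand)
    sizes = model.nb_size(mu)
    group_of_ind = [0] * n_individuals
    individual_ids = [f"ind{j}" for j in range(n_individuals)]
    cells_per_ind = draw_cells_per_individual(
        cell_count_mode, cells_per_individual, n_individuals, rng_cells
    )
    counts, mu_ij = _generate_counts(group_of_ind, mu[None, :], sizes[None, :],
                                     cells_per_ind, model, rng_ind, rng_nb)
    rates = draw_dropout_rates(model, n_genes, rng_drop_rates)
    counts = apply_dropout(counts, rates, rng_drop_mask)
    individual_of_cell, cell_ids = _cells_layout(individual_ids, cells_per_ind)
    return SimulatedDataset(
        counts=counts,
        gene_ids=[f"gene{i}" for i in range(n_genes)],
        cell_ids=cell_ids,
        individual_of_cell=individual_of_cell,
        individual_ids=individual_ids,
        phenotype_of_individual=np.zeros(n_individuals),
        de_flags=np.zeros(n_genes, dtype=bool),
        applied_effect=np.zeros(n_genes),
        kind="binary",
        design=None,
        grand_means=mu,
        individual_means=mu_ij,
    )
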
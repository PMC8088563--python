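import numpy as np
import pytest

import hierpower as hp
from hierpower.containers import SIZE_MAX, SimulationModel
from hierpower.simulate import (
    apply_dropout,
    apply_effect_binary,
    draw_cells_per_individual,
    draw_counts,
    draw_grand_means,
    draw_individual_means,
)


# ---------------------------------------------------------------------------
# building blocks

def test_fixed_cell_counts_are_constant():
    counts = draw_cells_per_individual("fixed", 100, 10, seed=0)
    assert counts.shape == (10,) and np.all(counts == 100)


def test_poisson_cell_counts_match_moments():
    n = 10_000
    counts = draw_cells_per_individual("poisson", 150, n, seed=1)
    se = np.sqrt(150 / n)
    assert counts.mean() == pytest.approx(150, abs=3 * se)
    assert counts.var() == pytest.approx(150, rel=0.05)


def test_negbin_cell_counts_match_moments_and_skip_zeros():
    n = 10_000
    counts = draw_cells_per_individual("negbin", 150, n, seed=2)
    assert np.all(counts >= 1)
    # NB variance mu + mu^2/size at size 1; zero-redraw barely perturbs it
    assert counts.var() == pytest.approx(150 + 150**2, rel=0.10)
    counts1 = draw_cells_per_individual("negbin", 1, 5_000, seed=3)
    assert np.all(counts1 >= 1)


def test_unknown_cell_mode_rejected():
    with pytest.raises(ValueError):
        draw_cells_per_individual("uniform", 10, 5, seed=0)


def test_grand_mean_draws_follow_fitted_gamma(truth_model):
    n = 100_000
    mu = draw_grand_means(truth_model, n, seed=4)
    shape, rate = truth_model.grand_mean_gamma
    assert np.all(mu > 0)
    se = np.sqrt(shape / rate**2 / n)
    assert mu.mean() == pytest.approx(shape / rate, abs=3 * se)
    np.testing.assert_array_equal(mu, draw_grand_means(truth_model, n, seed=4))


def test_fold_change_one_leaves_groups_identical(rng, truth_model):
    mu = rng.gamma(2, 50, 100)
    gm, applied = apply_effect_binary(mu, 1.0, np.ones(100, bool), seed=5)
    np.testing.assert_array_equal(gm[0], gm[1])
    assert np.all(np.abs(applied) == 1.0)


def test_fold_change_spikes_exactly_one_group(rng):
    mu = np.full(10_000, 10.0)
    gm, applied = apply_effect_binary(mu, 1.3, np.ones(10_000, bool), seed=6)
    spiked1 = applied > 0
    np.testing.assert_allclose(gm[1, spiked1], 13.0)
    np.testing.assert_allclose(gm[0, spiked1], 10.0)
    np.testing.assert_allclose(gm[0, ~spiked1], 13.0)
    # Bernoulli(0.5) direction balance within 3 binomial SE
    se = 0.5 / np.sqrt(10_000)
    assert spiked1.mean() == pytest.approx(0.5, abs=3 * se)


def test_null_genes_keep_identical_parameters(rng):
    mu = rng.gamma(2, 50, 50)
    flags = np.zeros(50, bool)
    flags[:25] = True
    gm, applied = apply_effect_binary(mu, 2.0, flags, seed=7)
    np.testing.assert_array_equal(gm[0, ~flags], gm[1, ~flags])
    assert np.all(applied[~flags] == 0)


def test_individual_means_degenerate_variance(truth_model):
    flat = SimulationModel(
        grand_mean_gamma=truth_model.grand_mean_gamma,
        f1=(0.0, 0.0), f2=truth_model.f2, dropout_gamma=truth_model.dropout_gamma,
    )
    means = draw_individual_means(40.0, flat, 50, seed=8)
    np.testing.assert_array_equal(means, np.full(50, 40.0))


def test_individual_means_match_normal_moments():
    model = SimulationModel(grand_mean_gamma=(1, 1), f1=(4.0, 0.0), f2=(4, 2),
                            dropout_gamma=(8, 17.78))
    n = 100_000
    means = draw_individual_means(1000.0, model, n, seed=9)  # truncation inactive
    assert means.var() == pytest.approx(4.0, rel=0.02)
    assert means.mean() == pytest.approx(1000.0, abs=3 * np.sqrt(4 / n))
    assert np.all(means >= 0)


def test_nb_counts_variance_identity(rng):
    draws = draw_counts(10.0, 5.0, 100_000, seed=10)
    assert draws.mean() == pytest.approx(10.0, rel=0.02)
    assert draws.var() == pytest.approx(10 + 100 / 5, rel=0.05)


def test_nb_counts_poisson_limit_at_cap():
    draws = draw_counts(10.0, SIZE_MAX, 100_000, seed=11)
    assert draws.var() == pytest.approx(draws.mean(), rel=0.05)


def test_zero_mean_yields_zero_counts():
    assert np.all(draw_counts(0.0, 5.0, 1000, seed=12) == 0)


def test_dropout_masking():
    counts = np.arange(1, 11, dtype=float)[None, :].repeat(3, axis=0)
    np.testing.assert_array_equal(apply_dropout(counts, [0.0, 0.0, 0.0], 13), counts)
    assert np.all(apply_dropout(counts, [1.0, 1.0, 1.0], 13) == 0)
    big = np.ones((1, 100_000))
    masked = apply_dropout(big, [0.3], 14)
    se = np.sqrt(0.3 * 0.7 / big.size)
    assert (masked == 0).mean() == pytest.approx(0.3, abs=3 * se)
    with pytest.raises(ValueError):
        apply_dropout(big, [1.5], 15)


# ---------------------------------------------------------------------------
# composed datasets

def test_binary_dataset_conserves_cells_and_is_deterministic(truth_model):
    design = hp.SimulationDesign(n_genes=12, n_per_group=10, cells_per_individual=100,
                                 fold_change=1.3, frac_de=0.5, seed=20)
    ds = hp.simulate_binary(design, truth_model)
    assert ds.counts.shape == (12, 2000)  # 2 x 10 individuals x 100 cells
    assert len(ds.individual_ids) == 20
    ds2 = hp.simulate_binary(design, truth_model)
    np.testing.assert_array_equal(ds.counts, ds2.counts)
    np.testing.assert_array_equal(ds.de_flags, ds2.de_flags)


def test_poisson_mode_conserves_realized_cells(truth_model):
    design = hp.SimulationDesign(n_genes=3, n_per_group=4, cells_per_individual=30,
                                 cell_count_mode="poisson", fold_change=1.0, seed=21)
    ds = hp.simulate_binary(design, truth_model)
    _, counts = np.unique(ds.individual_of_cell, return_counts=True)
    assert ds.counts.shape[1] == counts.sum()
    assert np.all(counts >= 1)


def test_fold_change_two_separates_group_means(truth_model):
    design = hp.SimulationDesign(n_genes=400, n_per_group=6, cells_per_individual=40,
                                 fold_change=2.0, frac_de=1.0, seed=22)
    ds = hp.simulate_binary(design, truth_model)
    grp = ds.phenotype_of_cell
    # over many genes the spiked/unspiked ratio of individual-mean averages
    # concentrates near the fold change
    m1 = ds.individual_means[:, 6:].mean(axis=1)
    m0 = ds.individual_means[:, :6].mean(axis=1)
    ratio = np.where(ds.applied_effect > 0, m1 / m0, m0 / m1)
    assert np.median(ratio) == pytest.approx(2.0, rel=0.1)
    assert grp.shape == (ds.n_cells,)


def test_fold_change_separation_is_monotone(truth_model):
    seps = []
    for fc in (1.0, 1.5, 2.5):
        design = hp.SimulationDesign(n_genes=600, n_per_group=4, cells_per_individual=1,
                                     fold_change=fc, frac_de=1.0, seed=23)
        ds = hp.simulate_binary(design, truth_model)
        m1 = ds.individual_means[:, 4:].mean(axis=1)
        m0 = ds.individual_means[:, :4].mean(axis=1)
        seps.append(np.mean(np.abs(np.log1p(m1) - np.log1p(m0))))
    assert seps[0] < seps[1] < seps[2]


def test_continuous_phenotype_targets_rho(truth_model):
    # individual-level correlation oracle at large n
    design = hp.SimulationDesign(n_genes=40, n_individuals=5000, cells_per_individual=1,
                                 rho=0.4, phenotype_mean=22, phenotype_sd=5, seed=24)
    ds = hp.simulate_continuous(design, truth_model)
    s = (ds.phenotype_of_individual - 22) / 5
    keep = ds.grand_means >= 20  # truncation at 0 inactive
    corrs = [np.corrcoef(ds.individual_means[i], s)[0, 1]
             for i in np.flatnonzero(keep & ds.de_flags)]
    # each sample correlation: 99% CI half-width ~ 2.58 * (1-rho^2)/sqrt(n)
    half = 2.58 * (1 - 0.4**2) / np.sqrt(5000)
    assert np.mean(corrs) == pytest.approx(0.4, abs=3 * half / np.sqrt(len(corrs)) + 0.01)
    assert np.median(np.abs(np.asarray(corrs) - 0.4) < 3 * half) == 1.0


def test_continuous_rho_high_shows_strong_signal(truth_model):
    design = hp.SimulationDesign(n_genes=8, n_individuals=60, cells_per_individual=100,
                                 rho=0.99, phenotype_mean=22, phenotype_sd=5, seed=25)
    ds = hp.simulate_continuous(design, truth_model)
    pheno = ds.phenotype_of_individual
    # rho is the individual-mean-level correlation: near 0.99 for every gene
    for i in np.flatnonzero(ds.de_flags):
        assert np.corrcoef(ds.individual_means[i], pheno)[0, 1] > 0.9
    # observable cell aggregates stay strongly correlated, attenuated by
    # within-individual NB + dropout noise (worst for high-dropout genes)
    corrs = []
    for i in np.flatnonzero(ds.de_flags):
        per_ind = [ds.counts[i][ds.individual_of_cell == ind].mean()
                   for ind in ds.individual_ids]
        corrs.append(np.corrcoef(per_ind, pheno)[0, 1])
    assert np.median(corrs) > 0.6 and min(corrs) > 0.3


def test_continuous_rho_zero_decouples_expression(truth_model):
    design = hp.SimulationDesign(n_genes=60, n_individuals=200, cells_per_individual=2,
                                 rho=0.0, phenotype_mean=22, phenotype_sd=5, seed=26)
    ds = hp.simulate_continuous(design, truth_model)
    s = (ds.phenotype_of_individual - 22) / 5
    corrs = np.array([np.corrcoef(ds.individual_means[i], s)[0, 1]
                      for i in range(ds.n_genes) if ds.individual_means[i].std() > 0])
    # mean of null correlations: SE = 1/sqrt(n_ind)/sqrt(n_genes)
    assert corrs.mean() == pytest.approx(0.0, abs=3 / np.sqrt(200 * corrs.size))


def test_pooled_moments_decompose_with_dropout_off(truth_model):
    # with dropout off, pooled mean tracks mu and pooled variance splits into
    # within (NB) + between (f1) components
    no_drop = SimulationModel(
        grand_mean_gamma=truth_model.grand_mean_gamma, f1=truth_model.f1,
        f2=truth_model.f2, dropout_gamma=(8.0, 8.0e8),
    )
    ds = hp.simulate_pilot(no_drop, n_genes=60, n_individuals=10,
                           cells_per_individual=1000, seed=27)
    keep = ds.grand_means >= 50
    mu = ds.grand_means[keep]
    pooled_mean = ds.counts[keep].mean(axis=1)
    assert np.median(np.abs(pooled_mean / mu - 1)) < 0.10
    size = no_drop.nb_size(mu)
    expect_var = mu + mu**2 / size + no_drop.inter_individual_variance(mu)
    ratio = ds.counts[keep].var(axis=1) / expect_var
    assert np.median(ratio) == pytest.approx(1.0, abs=0.10)
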
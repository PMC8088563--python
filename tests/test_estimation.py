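import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import hierpower as hp
from hierpower.containers import SIZE_MAX, ExpressionMatrix
from hierpower.estimation import (
    GeneParamTable,
    build_param_table,
    estimate_dispersion,
    estimate_dropout_rates,
    estimate_grand_means,
    estimate_inter_individual_variance,
    fit_model,
    fit_trend_line,
    prune_correlated_genes,
    _fit_gamma,
    _wls_line,
)


def _matrix(values, individuals):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(g)],
        cell_ids=[f"c{k}" for k in range(c)],
        individual_of_cell=np.asarray(individuals, dtype=object),
    )


# ---------------------------------------------------------------------------
# pruning

def _spearman_matrix(values):
    r, _ = scipy.stats.spearmanr(values, axis=1)
    if np.ndim(r) == 0:  # scipy collapses the 2-variable case to a scalar
        r = np.array([[1.0, float(r)], [float(r), 1.0]])
    return np.atleast_2d(r)


def _brute_force_prune(values, threshold, seed):
    """Replay the sequential rule with freshly computed Spearman coefficients."""
    g = values.shape[0]
    corr = _spearman_matrix(values)
    order = np.random.default_rng(seed).permutation(g)
    alive = np.ones(g, dtype=bool)
    for pos, gi in enumerate(order):
        if not alive[gi]:
            continue
        for gj in order[pos + 1:]:
            if alive[gj] and corr[gi, gj] > threshold:
                alive[gj] = False
    return np.flatnonzero(alive)


def test_duplicate_gene_pruned_to_single_survivor(rng):
    base = rng.gamma(2, 50, size=40)
    x = _matrix([base, base, rng.permutation(base)], ["A"] * 20 + ["B"] * 20)
    pruned = prune_correlated_genes(x, threshold=0.25, seed=0)
    # g0 and g1 are identical (Spearman 1): exactly one survives
    survivors = set(pruned.gene_ids)
    assert len(survivors & {"g0", "g1"}) == 1


def test_uncorrelated_genes_all_survive(rng):
    # independent heavy permutations: |Spearman| stays well under 0.25
    n = 400
    vals = np.vstack([rng.permutation(n).astype(float) for _ in range(6)])
    assert np.all(np.abs(_spearman_matrix(vals)[np.triu_indices(6, 1)]) <= 0.25)
    x = _matrix(vals, ["A"] * (n // 2) + ["B"] * (n // 2))
    assert prune_correlated_genes(x, 0.25, seed=3).n_genes == 6


@pytest.mark.parametrize("seed", [0, 1, 17])
def test_pruning_matches_brute_force_oracle(rng, seed):
    # 6 genes with a known correlation graph: pairs of noisy copies
    n = 60
    a, b, cvec = rng.gamma(2, 10, n), rng.gamma(2, 10, n), rng.gamma(2, 10, n)
    vals = np.vstack([
        a, a + rng.normal(0, 0.8, n),          # strongly linked pair
        b, b + rng.normal(0, 0.8, n),
        cvec, rng.permutation(cvec),           # unlinked pair
    ])
    x = _matrix(vals, ["A"] * 30 + ["B"] * 30)
    pruned = prune_correlated_genes(x, threshold=0.25, seed=seed)
    expected = {f"g{i}" for i in _brute_force_prune(vals, 0.25, seed)}
    assert set(pruned.gene_ids) == expected
    # invariant: no surviving pair exceeds the threshold
    c = _spearman_matrix(pruned.values)
    assert np.all(c[np.triu_indices(pruned.n_genes, 1)] <= 0.25)


def test_pruning_rejects_bad_threshold(small_pilot):
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValueError):
            prune_correlated_genes(small_pilot, threshold=bad, seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_pruned_set_never_contains_correlated_pair(seed):
    rng = np.random.default_rng(seed)
    n, g = 30, 8
    base = rng.gamma(2, 10, size=(g // 2, n))
    noisy = np.maximum(base + rng.normal(0, base.std() * 0.2, size=base.shape), 0.0)
    vals = np.vstack([base, noisy])
    x = _matrix(vals, ["A"] * 15 + ["B"] * 15)
    pruned = prune_correlated_genes(x, threshold=0.25, seed=seed)
    c = _spearman_matrix(pruned.values)
    if pruned.n_genes > 1:
        assert np.all(c[np.triu_indices(pruned.n_genes, 1)] <= 0.25 + 1e-12)


# ---------------------------------------------------------------------------
# grand means

def test_grand_mean_constant_gene_is_exact():
    x = _matrix([[7.0] * 6], ["A", "A", "B", "B", "C", "C"])
    got = estimate_grand_means(x, n_resamples=25, seed=0)
    assert got[0] == pytest.approx(7.0, abs=0)


def test_grand_mean_within_individual_constants_force_midpoint():
    x = _matrix([[1.0, 1.0, 3.0, 3.0]], ["A", "A", "B", "B"])
    got = estimate_grand_means(x, n_resamples=10, seed=1)
    assert got[0] == pytest.approx(2.0, abs=0)


def test_grand_mean_one_cell_per_individual_is_plain_mean():
    vals = np.array([[2.0, 5.0, 11.0], [1.0, 1.0, 4.0]])
    x = _matrix(vals, ["A", "B", "C"])
    got = estimate_grand_means(x, n_resamples=3, seed=2)
    np.testing.assert_allclose(got, vals.mean(axis=1), rtol=0, atol=0)


def _exhaustive_grand_mean(values_row, groups, nonzero_only):
    """Exact expectation over all one-cell-per-individual draws."""
    cells = [np.flatnonzero(np.asarray(groups) == g)
             for g in dict.fromkeys(groups)]
    totals, count = 0.0, 0
    for combo in itertools.product(*cells):
        draw = values_row[list(combo)]
        if nonzero_only:
            nz = draw[draw > 0]
            if nz.size == 0:
                continue
            totals += nz.mean()
        else:
            totals += draw.mean()
        count += 1
    return totals / count


@pytest.mark.parametrize("nonzero_only", [True, False])
def test_grand_mean_matches_exhaustive_enumeration(nonzero_only):
    groups = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
    row = np.array([4.0, 8, 0, 6, 2, 4, 9, 0, 3])
    x = _matrix([row], groups)
    exact = _exhaustive_grand_mean(row, groups, nonzero_only)
    n_res = 40_000
    got = estimate_grand_means(x, n_resamples=n_res, seed=5, nonzero_only=nonzero_only)[0]
    # per-replicate values live in [0, 9]: 3 MC standard errors with sd <= 3
    assert got == pytest.approx(exact, abs=3 * 3.0 / np.sqrt(n_res))


def test_grand_mean_rejects_bad_resamples(small_pilot):
    with pytest.raises(ValueError):
        estimate_grand_means(small_pilot, n_resamples=0, seed=0)


# ---------------------------------------------------------------------------
# inter-individual variance / dispersion / dropout

def test_inter_individual_variance_cases():
    x = _matrix(
        [
            [2.0, 4.0, 0.0, 6.0, 6.0, 6.0, 0.0, 0.0, 3.0],  # means 3, 6, 3
            [5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0],  # identical means
            [2.0, 2.0, 0.0, 4.0, 4.0, 4.0, 0.0, 0.0, 0.0],  # means 2, 4
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 9.0],  # one individual only
        ],
        ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
    )
    assert estimate_inter_individual_variance(x, 0) == pytest.approx(3.0)
    assert estimate_inter_individual_variance(x, 1) == 0.0
    assert estimate_inter_individual_variance(x, 2) == pytest.approx(2.0)
    assert np.isnan(estimate_inter_individual_variance(x, 3))


def test_inter_individual_variance_matches_zero_dropping_oracle(rng):
    vals = rng.poisson(6, size=(1, 30)).astype(float)
    groups = np.repeat(["A", "B", "C"], 10)
    x = _matrix(vals, groups)
    means = [vals[0][(groups == g) & (vals[0] > 0)].mean() for g in "ABC"]
    assert estimate_inter_individual_variance(x, 0) == pytest.approx(np.var(means, ddof=1))


def test_dispersion_poisson_boundary_is_capped_and_flagged():
    size, capped = estimate_dispersion(3.0, 3.0)
    assert capped and size == SIZE_MAX
    size, capped = estimate_dispersion(10.0, 5.0)  # underdispersed
    assert capped and size == SIZE_MAX


def test_dispersion_moment_matching(rng):
    size, capped = estimate_dispersion(4.0, 8.0)
    assert not capped and size == pytest.approx(4.0)
    # NB(mean 4, size 4) reproduces variance 8
    draws = rng.negative_binomial(4, 4 / (4 + 4), size=200_000)
    assert draws.var() == pytest.approx(8.0, rel=0.03)


def test_dispersion_rejects_nonpositive_inputs():
    for m, v in [(0.0, 1.0), (1.0, 0.0), (-2.0, 3.0)]:
        with pytest.raises(ValueError):
            estimate_dispersion(m, v)


def test_dropout_rates_are_zero_fractions():
    x = _matrix(
        [[1, 2, 3, 4], [0, 0, 0, 0], [0, 5, 0, 6]],
        ["A", "A", "B", "B"],
    )
    np.testing.assert_allclose(estimate_dropout_rates(x), [0.0, 1.0, 0.5])


# ---------------------------------------------------------------------------
# hyper-distribution fits

def test_trend_line_fits_exact_points():
    intercept, slope, n = fit_trend_line([0.0, 1.0, 2.0], [1.0, 3.0, 5.0], "f1")
    assert (intercept, slope, n) == (pytest.approx(1.0), pytest.approx(2.0), 3)
    mu = np.array([20.0, 45.0, 110.0, 300.0])
    a, b, _ = _wls_line(np.log(mu), 0.5 + 1.0 * np.log(mu), "f2")
    assert a == pytest.approx(0.5, abs=1e-9) and b == pytest.approx(1.0, abs=1e-9)


def test_trend_line_rejects_degenerate_x():
    with pytest.raises(ValueError):
        fit_trend_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "f1")


def test_gamma_mle_recovers_known_shape(rng):
    draws = rng.gamma(2.0, 1.0, size=10_000)
    shape, rate = _fit_gamma(draws, truncate_at=None, min_genes=30)
    assert shape == pytest.approx(2.0, abs=0.1)
    assert rate == pytest.approx(1.0, abs=0.1)


def test_truncated_gamma_mle_recovers_full_distribution(rng):
    draws = rng.gamma(1.2, 1 / 0.012, size=20_000)
    shape, rate = _fit_gamma(draws, truncate_at=20.0, min_genes=30)
    assert shape == pytest.approx(1.2, rel=0.05)
    assert rate == pytest.approx(0.012, rel=0.05)


def _exact_table(mu, f1_int, f1_slope, f2_a, f2_b, n_cells=10**9):
    """A GeneParamTable whose trend points sit exactly on the target lines."""
    size = f2_a + f2_b * np.log(mu)
    within = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(mu.size)],
            "individual_id": "A",
            "n_nonzero": n_cells,     # sampling-noise correction ~ 0
            "within_mean": mu,
            "within_var": mu + mu**2 / size,
            "dispersion": size,
            "capped": False,
        }
    )
    genes = pd.DataFrame(
        {
            "grand_mean": mu,
            "inter_indiv_var": f1_int + f1_slope * mu,
            "dropout_rate": np.linspace(0.2, 0.7, mu.size),
        },
        index=pd.Index([f"g{i}" for i in range(mu.size)], name="gene_id"),
    )
    return GeneParamTable(genes=genes, within=within)


def test_fit_model_recovers_exact_trends():
    mu = np.linspace(25, 300, 40)
    model = fit_model(_exact_table(mu, 1.0, 2.0, 0.5, 1.0))
    assert model.f1[0] == pytest.approx(1.0, abs=1e-4)
    assert model.f1[1] == pytest.approx(2.0, abs=1e-6)
    assert model.f2[0] == pytest.approx(0.5, abs=1e-6)
    assert model.f2[1] == pytest.approx(1.0, abs=1e-6)


def test_fit_model_rejects_degenerate_tables():
    mu = np.full(40, 50.0)
    table = _exact_table(np.linspace(25, 300, 40), 1.0, 2.0, 0.5, 1.0)
    table.genes["grand_mean"] = mu  # constant grand means
    with pytest.raises(ValueError):
        fit_model(table)
    with pytest.raises(ValueError):
        fit_model(_exact_table(np.linspace(25, 300, 10), 1, 2, 0.5, 1.0))  # too few


def test_build_param_table_matches_per_gene_estimators(small_pilot):
    table = build_param_table(small_pilot, n_resamples=50, seed=4)
    np.testing.assert_allclose(
        table.genes["dropout_rate"].to_numpy(), estimate_dropout_rates(small_pilot)
    )
    for gene in (0, 17, 123):
        expected = estimate_inter_individual_variance(small_pilot, gene)
        got = table.genes["inter_indiv_var"].iloc[gene]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)
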
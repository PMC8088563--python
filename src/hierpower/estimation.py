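"""Estimate the generative model of hierarchical single-cell expression.

The pipeline mirrors how a pilot matrix is turned into simulator inputs:

1. prune genes down to a mutually uncorrelated set (Spearman threshold),
   so trend fits are not driven by co-expressed blocks;
2. estimate per-gene grand means by repeatedly sampling one cell per
   individual (decoupling the mean from the within-individual correlation);
3. estimate inter-individual variance as the variance of per-individual
   means of non-zero values;
4. estimate within-individual NB dispersion from non-zero means/variances;
5. estimate per-gene dropout as the fraction of zero cells;
6. fit the hyper-distributions: gamma MLE for grand means, a linear trend
   f1 (inter-individual variance on grand mean), a logarithmic trend f2
   (NB size on log mean), and a gamma MLE for dropout rates.

All abundance parameters are computed from non-zero (detected) values;
dropout is modeled separately. Grand-mean resampling therefore averages the
non-zero values among the sampled cells by default (``nonzero_only=True``);
pass ``False`` for the plain mean over all sampled cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .containers import ExpressionMatrix, SimulationModel, SIZE_MAX, SIZE_MIN, RATE_EPS

#: Genes whose mean estimates fall below this floor are excluded from the
#: hyper-parameter fits. Non-zero-conditioned moment estimators are only
#: calibrated above ~20 TPM: below that, count discreteness (non-zero values
#: are >= 1), NB zero mass and detection selection across individuals
#: inflate the estimated means and deflate excess variances. Restricting the
#: trend fits on the regressor does not bias least squares, and the gamma
#: fit accounts for the restriction with a truncated likelihood.
MIN_TREND_MEAN = 20.0

__all__ = [
    "GeneParamTable",
    "prune_correlated_genes",
    "estimate_grand_means",
    "estimate_inter_individual_variance",
    "estimate_dispersion",
    "estimate_dropout_rates",
    "build_param_table",
    "fit_model",
    "estimate_model",
]


# ---------------------------------------------------------------------------
# gene pruning

def _standardized_ranks(values: np.ndarray) -> np.ndarray:
    """Midrank-transform each gene and standardize; constant genes -> 0 rows.

    With this transform the Pearson correlation of two rows equals the
    Spearman correlation of the original genes.
    """
    ranks = scipy.stats.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, ranks / norm, 0.0)
    return z


def prune_correlated_genes(
    x: ExpressionMatrix, threshold: float = 0.25, seed: int = 0
) -> ExpressionMatrix:
    """Sequentially prune genes until no pair has Spearman correlation > threshold.

    Genes are visited in a seeded random order; each surviving visited gene
    removes every not-yet-visited gene correlated with it above the
    threshold. Constant genes have undefined correlation and are treated as
    uncorrelated (never removed on correlation grounds).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    g = x.n_genes
    if g < 2:
        raise ValueError("need at least 2 genes to prune")

    z = _standardized_ranks(x.values)
    rng = np.random.default_rng(seed)
    order = rng.permutation(g)

    alive = np.ones(g, dtype=bool)
    # full g x g correlation via one matmul when memory allows, else per-gene
    use_full = g <= 8192
    corr_full = (z @ z.T) if use_full else None
    for pos, gi in enumerate(order):
        if not alive[gi]:
            continue
        corr = corr_full[gi] if use_full else z @ z[gi]
        later = order[pos + 1:]
        doomed = later[(corr[later] > threshold) & alive[later]]
        alive[doomed] = False
    keep = np.flatnonzero(alive)
    return x.subset_genes(keep)


# ---------------------------------------------------------------------------
# per-gene estimators

def estimate_grand_means(
    x: ExpressionMatrix,
    n_resamples: int = 1000,
    seed: int = 0,
    nonzero_only: bool = True,
) -> np.ndarray:
    """Resampled grand means: one random cell per individual, averaged.

    Each replicate draws one cell uniformly from every individual (the same
    cell indices are reused across genes) and averages the gene's values
    over the draw; the grand mean is the mean of those replicate means.
    With ``nonzero_only`` (default) each replicate averages only the
    non-zero sampled values, keeping the abundance estimate independent of
    dropout; genes with no non-zero sample in any replicate get 0.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(seed)
    cell_groups = [x.cells_of(ind) for ind in x.individuals]
    n_ind = len(cell_groups)
    g = x.n_genes

    sums = np.zeros(g)
    counts = np.zeros(g)
    chunk = max(1, min(n_resamples, 2_000_000 // max(1, g)))
    done = 0
    while done < n_resamples:
        r = min(chunk, n_resamples - done)
        # (r, n_ind) sampled cell columns, shared across genes
        idx = np.column_stack([grp[rng.integers(0, len(grp), size=r)] for grp in cell_groups])
        sub = x.values[:, idx.ravel()].reshape(g, r, n_ind)
        if nonzero_only:
            nz = sub > 0
            n_nz = nz.sum(axis=2)
            with np.errstate(invalid="ignore"):
                rep_means = np.where(n_nz > 0, sub.sum(axis=2) / np.maximum(n_nz, 1), np.nan)
            valid = n_nz > 0
            sums += np.where(valid, rep_means, 0.0).sum(axis=1)
            counts += valid.sum(axis=1)
        else:
            sums += sub.mean(axis=2).sum(axis=1)
            counts += r
        done += r

    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out


def estimate_inter_individual_variance(x: ExpressionMatrix, gene: int) -> float:
    """Sample variance (ddof=1) of per-individual means of non-zero values.

    Returns NaN (the undefined sentinel) when fewer than 2 individuals have
    a non-zero cell for the gene; such genes are excluded from f1 fitting.
    """
    row = x.values[gene]
    means = []
    for ind in x.individuals:
        vals = row[x.cells_of(ind)]
        vals = vals[vals > 0]
        if vals.size:
            means.append(vals.mean())
    if len(means) < 2:
        return float("nan")
    return float(np.var(means, ddof=1))


def estimate_dispersion(within_mean: float, within_var: float) -> tuple[float, bool]:
    """Method-of-moments NB size from non-zero within-individual moments.

    size = mean^2 / (var - mean) when var > mean. At or below the Poisson
    boundary (var <= mean, zero or negative excess dispersion) the size is
    capped at SIZE_MAX and flagged: returns ``(size, capped)``.
    """
    if not (within_mean > 0) or not (within_var > 0):
        raise ValueError("within_mean and within_var must be positive")
    if within_var <= within_mean:
        return SIZE_MAX, True
    return float(within_mean**2 / (within_var - within_mean)), False


def estimate_dropout_rates(x: ExpressionMatrix) -> np.ndarray:
    """Per-gene proportion of cells with value exactly zero."""
    return (x.values == 0).mean(axis=1)


# ---------------------------------------------------------------------------
# assembling the per-gene table

@dataclass
class GeneParamTable:
    """Per-gene and per-(gene, individual) estimates feeding the model fit.

    genes : DataFrame indexed by gene_id with columns grand_mean,
        inter_indiv_var (NaN when < 2 individuals qualify), dropout_rate.
    within : long DataFrame with one row per (gene, individual) having
        >= 2 non-zero cells: n_nonzero, within_mean, within_var,
        dispersion, capped.
    """

    genes: pd.DataFrame
    within: pd.DataFrame


def build_param_table(
    x: ExpressionMatrix, n_resamples: int = 1000, seed: int = 0
) -> GeneParamTable:
    """Compute every per-gene estimate on an (already pruned) matrix."""
    grand = estimate_grand_means(x, n_resamples=n_resamples, seed=seed)
    dropout = estimate_dropout_rates(x)

    groups = [(ind, x.cells_of(ind)) for ind in x.individuals]
    g = x.n_genes

    # vectorized per-individual non-zero moments
    ind_means = np.full((g, len(groups)), np.nan)
    rows: dict[str, list] = {k: [] for k in
                             ("gene_id", "individual_id", "n_nonzero",
                              "within_mean", "within_var", "dispersion", "capped")}
    for j, (ind, cols) in enumerate(groups):
        sub = x.values[:, cols]
        nz = sub > 0
        n_nz = nz.sum(axis=1)
        s = sub.sum(axis=1)
        ss = (sub**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_nz = np.where(n_nz > 0, s / np.maximum(n_nz, 1), np.nan)
            var_nz = np.where(
                n_nz > 1,
                (ss - np.maximum(n_nz, 1) * mean_nz**2) / np.maximum(n_nz - 1, 1),
                np.nan,
            )
        var_nz = np.where(var_nz < 0, 0.0, var_nz)  # numerical guard
        ind_means[:, j] = mean_nz
        ok = (n_nz > 1) & (mean_nz > 0)
        for i in np.flatnonzero(ok):
            if var_nz[i] > 0:
                size, capped = estimate_dispersion(float(mean_nz[i]), float(var_nz[i]))
            else:
                size, capped = SIZE_MAX, True  # constant non-zero values
            rows["gene_id"].append(x.gene_ids[i])
            rows["individual_id"].append(ind)
            rows["n_nonzero"].append(int(n_nz[i]))
            rows["within_mean"].append(float(mean_nz[i]))
            rows["within_var"].append(float(var_nz[i]))
            rows["dispersion"].append(size)
            rows["capped"].append(capped)

    n_qual = np.sum(~np.isnan(ind_means), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        inter_var = np.where(n_qual >= 2, np.nanvar(ind_means, axis=1, ddof=1), np.nan)

    genes = pd.DataFrame(
        {"grand_mean": grand, "inter_indiv_var": inter_var, "dropout_rate": dropout},
        index=pd.Index(x.gene_ids, name="gene_id"),
    )
    return GeneParamTable(genes=genes, within=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hyper-distribution fits

def fit_trend_line(xv, yv, what: str = "trend") -> tuple[float, float, int]:
    """Least-squares line y = intercept + slope * x on finite points."""
    xv = np.asarray(xv, dtype=float)
    yv = np.asarray(yv, dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if xv.size < 2 or np.unique(xv).size < 2:
        raise ValueError(f"degenerate input for {what}: need >= 2 distinct x-values")
    slope, intercept = np.polyfit(xv, yv, 1)
    return float(intercept), float(slope), int(xv.size)


def _f1_points(params: GeneParamTable) -> tuple[np.ndarray, np.ndarray]:
    """(grand mean, noise-corrected inter-individual variance) per gene.

    The raw variance of per-individual means estimates the biological
    inter-individual variance PLUS the sampling variance of each mean
    (within-variance / n cells) — a super-linear-in-mean term that would
    tilt the trend. The one-way ANOVA moment correction subtracts the
    average within-individual sampling variance.
    """
    w = params.within
    noise = (w["within_var"] / w["n_nonzero"]).groupby(w["gene_id"]).mean()
    gm = params.genes["grand_mean"]
    raw = params.genes["inter_indiv_var"]
    corr = noise.reindex(params.genes.index).fillna(0.0)
    return gm.to_numpy(dtype=float), (raw - corr).to_numpy(dtype=float)


def _f2_points(params: GeneParamTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log mean, pooled NB size, x noise variance) per gene.

    The per-(gene, individual) moment ratio m^2/(v - m) is consistent but
    heavy-tailed at pilot cell counts (the denominator is noisy near the
    Poisson boundary), so the trend is fitted to per-gene pooled moments:
    size_i = mean_j(m_ij^2) / mean_j(v_ij - m_ij). Pooling the numerator
    and denominator across individuals before dividing tames the ratio's
    tail; the remaining second-order (delta-method) ratio bias is divided
    out using the observed between-individual spread of the moments. Genes
    whose pooled excess variance is not positive (Poisson-like) carry no
    dispersion information and are excluded. The third return value is the
    estimated sampling variance of each log-mean regressor, used for the
    errors-in-variables slope correction in the trend fit.
    """
    w = params.within
    pts = []
    for _, d in w.groupby("gene_id", sort=False):
        m = d["within_mean"].to_numpy(dtype=float)
        v = d["within_var"].to_numpy(dtype=float)
        J = m.size
        num, den = m**2, v - m
        nbar, dbar = num.mean(), den.mean()
        if dbar <= 0:
            continue
        corr = 1.0
        if J >= 3:
            var_d = den.var(ddof=1)
            cov_nd = np.cov(num, den, ddof=1)[0, 1]
            corr = float(np.clip(1.0 + var_d / (J * dbar**2) - cov_nd / (J * nbar * dbar),
                                 0.5, 2.0))
        mbar = m.mean()
        x_noise = m.var(ddof=1) / (J * mbar**2) if J >= 2 else 0.0
        pts.append((np.log(mbar), (nbar / dbar) / corr, x_noise))
    if not pts:
        return np.array([]), np.array([]), np.array([])
    arr = np.asarray(pts)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _fit_gamma(values: np.ndarray, truncate_at: float | None, min_genes: int) -> tuple[float, float]:
    """Gamma MLE of positive values, honoring a lower truncation point.

    When the sample is restricted to values >= truncate_at (the calibrated
    region of the mean estimator), the likelihood of each point is
    pdf(x) / sf(truncate_at) so the full-distribution shape and rate are
    still identified. Falls back to the plain MLE when too few values sit
    above the truncation point (e.g. data on a much smaller scale).
    """
    kept = values[values >= truncate_at] if truncate_at else values
    if truncate_at and kept.size >= max(min_genes, 0.2 * values.size):
        shape0, _, scale0 = scipy.stats.gamma.fit(kept, floc=0)

        def nll(theta):
            a, r = np.exp(theta)
            return -(
                np.sum(scipy.stats.gamma.logpdf(kept, a, scale=1.0 / r))
                - kept.size * scipy.stats.gamma.logsf(truncate_at, a, scale=1.0 / r)
            )

        res = scipy.optimize.minimize(
            nll, np.log([shape0, 1.0 / scale0]), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000},
        )
        if res.success:
            a, r = np.exp(res.x)
            return float(a), float(r)
    shape, _, scale = scipy.stats.gamma.fit(values, floc=0)
    return float(shape), float(1.0 / scale)


def _wls_line(xv, yv, what: str, x_noise_var=None) -> tuple[float, float, int]:
    """Two-pass weighted least squares for trends whose residual scale grows
    with the trend level (constant relative error); the first OLS pass sets
    the weights. With ``x_noise_var`` (known per-point sampling variance of
    the regressor) the slope is de-attenuated by the classical
    errors-in-variables reliability ratio and the intercept recomputed
    through the weighted means. Exact-line inputs are recovered exactly."""
    intercept, slope, n = fit_trend_line(xv, yv, what)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = np.asarray(xv, float)[ok], np.asarray(yv, float)[ok]
    pred = intercept + slope * xv
    scale = np.maximum(np.abs(pred), 0.05 * np.median(np.abs(yv)) + 1e-12)
    w = 1.0 / scale
    slope, intercept = np.polyfit(xv, yv, 1, w=w)
    if x_noise_var is not None and xv.size > 2:
        w2 = (w**2)[: xv.size] / np.sum(w**2)
        xbar = np.sum(w2 * xv)
        ybar = np.sum(w2 * yv)
        sxx = np.sum(w2 * (xv - xbar) ** 2)
        noise = np.sum(w2 * np.asarray(x_noise_var, float)[ok])
        if 0 < noise < 0.5 * sxx:
            slope = slope * sxx / (sxx - noise)
            intercept = ybar - slope * xbar
    return float(intercept), float(slope), n


def fit_model(params: GeneParamTable, min_genes: int = 30) -> SimulationModel:
    """Fit the simulator hyper-parameters from a per-gene estimate table.

    gamma MLE (floc=0) on positive grand means; f1 by least squares of the
    noise-corrected inter-individual variance on the grand mean; f2 by
    least squares of the per-gene pooled NB size on the log within-mean
    (see :func:`_f1_points` / :func:`_f2_points` for why the points are
    stabilized first); gamma MLE on dropout rates nudged into (0, 1).
    """
    gm = params.genes["grand_mean"].to_numpy(dtype=float)
    pos = gm[np.isfinite(gm) & (gm > 0)]
    if pos.size < min_genes:
        raise ValueError(f"need >= {min_genes} genes with positive grand means; got {pos.size}")
    if np.ptp(pos) == 0:
        raise ValueError("degenerate input: grand means are constant")

    f2_x, f2_y, f2_noise = _f2_points(params)
    keep2 = np.exp(f2_x) >= MIN_TREND_MEAN
    f2_a, f2_b, n_f2 = _wls_line(f2_x[keep2], f2_y[keep2], "f2", x_noise_var=f2_noise[keep2])

    f1_x, f1_y = _f1_points(params)
    keep1 = f1_x >= MIN_TREND_MEAN
    f1_int, f1_slope, n_f1 = _wls_line(f1_x[keep1], f1_y[keep1], "f1")

    grand_gamma = _fit_gamma(pos, MIN_TREND_MEAN, min_genes)

    rates = params.genes["dropout_rate"].to_numpy(dtype=float)
    rates = np.clip(rates, RATE_EPS, 1.0 - RATE_EPS)
    if np.ptp(rates) == 0:
        raise ValueError("degenerate input: dropout rates are constant")
    d_shape, _, d_scale = scipy.stats.gamma.fit(rates, floc=0)
    dropout_gamma = (float(d_shape), float(1.0 / d_scale))

    return SimulationModel(
        grand_mean_gamma=grand_gamma,
        f1=(f1_int, f1_slope),
        f2=(f2_a, f2_b),
        dropout_gamma=dropout_gamma,
        provenance={
            "n_genes_gamma": int(pos.size),
            "n_genes_f1": n_f1,
            "n_genes_f2": n_f2,
            "size_cap": SIZE_MAX,
        },
    )


def estimate_model(
    x: ExpressionMatrix,
    prune_threshold: float = 0.25,
    n_resamples: int = 1000,
    seed: int = 0,
) -> SimulationModel:
    """Full pipeline: prune, estimate per-gene parameters, fit the model."""
    pruned = prune_correlated_genes(x, threshold=prune_threshold, seed=seed)
    table = build_param_table(pruned, n_resamples=n_resamples, seed=seed + 1)
    model = fit_model(table)
    model.provenance.update(
        {
            "source": f"{x.n_genes} genes x {x.n_cells} cells, {len(x.individuals)} individuals",
            "n_genes_after_pruning": pruned.n_genes,
            "prune_threshold": prune_threshold,
            "n_resamples": n_resamples,
            "seed": seed,
        }
    )
    return model
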
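"""Per-gene differential-expression tests for hierarchical single-cell data.

The recommended test is a two-part hurdle model with a per-individual
random intercept: a mixed logistic regression on the expression indicator
(is the gene detected in the cell?) plus a linear mixed model on the
log(x+1) expression of the detected cells. Each component is tested for the
predictor coefficient (LRT by default, Wald optionally); the two chi-square
statistics and their degrees of freedom are summed — the components are
conditionally independent, so the sum stays chi-square under the null.

Setting ``random_effects=False`` gives the naive cells-as-independent
hurdle (plain logistic + OLS), which ignores the nesting of cells within
individuals. ``pseudobulk_test`` collapses each individual to one aggregate
value and tests at the individual level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
import statsmodels.api as sm

from ._glmm import fit_mixed_logit
from ._lmm import fit_mixed_lm

__all__ = ["HurdleFit", "log1_transform", "combine_components", "fit_hurdle", "pseudobulk_test"]


def log1_transform(values) -> np.ndarray:
    """Elementwise natural log(x + 1); rejects negative input."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("log1 transform requires non-negative values")
    return np.log1p(values)


def combine_components(stat_d: float, df_d: int, stat_c: float, df_c: int):
    """Sum component chi-square statistics and degrees of freedom.

    Returns (stat, df, p) with p the upper-tail chi-square probability;
    df = 0 yields p = 1 (no information).
    """
    if stat_d < 0 or stat_c < 0:
        raise ValueError("component statistics must be non-negative")
    stat = stat_d + stat_c
    df = df_d + df_c
    p = float(scipy.stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return stat, df, p


@dataclass
class HurdleFit:
    """Result of a two-part hurdle fit on one gene."""

    stat_discrete: float
    df_discrete: int
    stat_continuous: float
    df_continuous: int
    stat_combined: float
    df_combined: int
    p_value: float
    converged_discrete: bool
    converged_continuous: bool
    test_type: str
    random_effects: bool
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.converged_discrete and self.converged_continuous and np.isfinite(self.p_value)


def _encode_predictor(predictor, n: int) -> np.ndarray:
    x = np.asarray(predictor)
    if x.shape != (n,):
        raise ValueError("predictor must have one value per cell")
    if x.dtype.kind not in "fiu":
        levels = np.unique(x)
        if levels.size != 2:
            raise ValueError("non-numeric predictors must have exactly 2 levels")
        x = (x == levels[1]).astype(float)
    return np.asarray(x, dtype=float)


def _lrt_stat(llf_full: float, llf_null: float) -> float:
    stat = 2.0 * (llf_full - llf_null)
    # independent optimizations can land epsilon below the null; clamp
    return max(float(stat), 0.0)


def _discrete_component(z, x, groups, random_effects, test_type):
    """(stat, df, converged, flags) for the detection (logistic) part."""
    flags: list[str] = []
    if z.all() or not z.any():
        return 0.0, 0, True, ["discrete_degenerate"]
    X_full = np.column_stack([np.ones(z.size), x])
    X_null = np.ones((z.size, 1))
    try:
        if random_effects:
            full = fit_mixed_logit(z.astype(float), X_full, groups)
            if test_type == "lrt":
                null = fit_mixed_logit(z.astype(float), X_null, groups)
                if full.converged and null.converged:
                    return _lrt_stat(full.loglik, null.loglik), 1, True, flags
                flags.append("discrete_wald_fallback")
            full = fit_mixed_logit(z.astype(float), X_full, groups, compute_bse=True)
            if full.converged and full.bse is not None and full.bse[1] > 0:
                if test_type == "lrt":
                    flags.append("discrete_wald_fallback")
                return float((full.params[1] / full.bse[1]) ** 2), 1, True, flags
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                full = sm.GLM(z.astype(float), X_full, family=sm.families.Binomial()).fit()
                if test_type == "lrt":
                    null = sm.GLM(z.astype(float), X_null, family=sm.families.Binomial()).fit()
                    if np.isfinite(full.llf) and np.isfinite(null.llf):
                        return _lrt_stat(full.llf, null.llf), 1, True, flags
                    flags.append("discrete_wald_fallback")
                if np.isfinite(full.bse[1]) and full.bse[1] > 0:
                    if test_type == "lrt" and "discrete_wald_fallback" not in flags:
                        flags.append("discrete_wald_fallback")
                    return float((full.params[1] / full.bse[1]) ** 2), 1, True, flags
    except Exception:
        pass
    flags.append("discrete_failed")
    return 0.0, 0, False, flags


def _continuous_component(y, x, groups, random_effects, test_type):
    """(stat, df, converged, flags) for the Gaussian part on detected cells."""
    flags: list[str] = []
    if y.size < 4 or np.unique(x).size < 2:
        return 0.0, 0, True, ["continuous_degenerate"]
    X_full = np.column_stack([np.ones(y.size), x])
    X_null = np.ones((y.size, 1))
    try:
        if random_effects and np.unique(groups).size >= 2:
            full = fit_mixed_lm(y, X_full, groups)
            if test_type == "lrt":
                null = fit_mixed_lm(y, X_null, groups)
                if full.converged and null.converged:
                    return _lrt_stat(full.loglik, null.loglik), 1, True, flags
                flags.append("continuous_wald_fallback")
            if full.converged and np.isfinite(full.bse[1]) and full.bse[1] > 0:
                if test_type == "lrt" and "continuous_wald_fallback" not in flags:
                    flags.append("continuous_wald_fallback")
                return float((full.params[1] / full.bse[1]) ** 2), 1, True, flags
        else:
            if random_effects:
                flags.append("continuous_ols_fallback")
            full = sm.OLS(y, X_full).fit()
            if test_type == "lrt":
                null = sm.OLS(y, X_null).fit()
                return _lrt_stat(full.llf, null.llf), 1, True, flags
            if np.isfinite(full.bse[1]) and full.bse[1] > 0:
                return float((full.params[1] / full.bse[1]) ** 2), 1, True, flags
    except Exception:
        pass
    flags.append("continuous_failed")
    return 0.0, 0, False, flags


def fit_hurdle(
    gene_values,
    predictor,
    individual_of_cell,
    random_effects: bool = True,
    test_type: str = "lrt",
) -> HurdleFit:
    """Two-part hurdle test of one gene against a per-cell predictor.

    The discrete part models the detection indicator (mixed logistic when
    ``random_effects``); the continuous part models log(x+1) on the detected
    cells only (linear mixed model / OLS). Degenerate components (all-zero
    gene, all cells detected, too few detected cells) contribute statistic 0
    with 0 df and are flagged rather than failed.
    """
    if test_type not in ("lrt", "wald"):
        raise ValueError("test_type must be 'lrt' or 'wald'")
    values = np.asarray(gene_values, dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    x = _encode_predictor(predictor, values.size)
    if np.unique(x).size < 2:
        raise ValueError("predictor is constant")
    groups = np.asarray(individual_of_cell)
    if random_effects and np.unique(groups).size < 2:
        raise ValueError("random effects need >= 2 individuals")

    z = values > 0
    if not z.any():
        return HurdleFit(0.0, 0, 0.0, 0, 0.0, 0, 1.0, True, True,
                         test_type, random_effects, ["all_zero"])

    stat_d, df_d, conv_d, flags_d = _discrete_component(z, x, groups, random_effects, test_type)
    y = log1_transform(values[z])
    stat_c, df_c, conv_c, flags_c = _continuous_component(
        y, x[z], groups[z], random_effects, test_type
    )
    stat, df, p = combine_components(stat_d, df_d, stat_c, df_c)
    return HurdleFit(
        stat_discrete=stat_d, df_discrete=df_d,
        stat_continuous=stat_c, df_continuous=df_c,
        stat_combined=stat, df_combined=df, p_value=p,
        converged_discrete=conv_d, converged_continuous=conv_c,
        test_type=test_type, random_effects=random_effects,
        flags=flags_d + flags_c,
    )


def _aggregate(values, individual_of_cell, aggregation: str):
    groups = np.asarray(individual_of_cell)
    labels = list(dict.fromkeys(groups))
    agg = np.empty(len(labels))
    for j, lab in enumerate(labels):
        v = np.asarray(values, dtype=float)[groups == lab]
        if aggregation == "mean_log":
            agg[j] = log1_transform(v).mean()
        elif aggregation == "log_of_mean":
            agg[j] = float(np.log1p(v.mean()))
        elif aggregation == "nonzero_mean":
            nz = v[v > 0]
            agg[j] = log1_transform(nz).mean() if nz.size else 0.0
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return labels, agg


def pseudobulk_test(
    gene_values,
    predictor,
    individual_of_cell,
    kind: str | None = None,
    aggregation: str = "mean_log",
):
    """Individual-level test after collapsing cells to one value per donor.

    Aggregates each individual's cells (mean of log(x+1) by default), then a
    two-sample Welch t-test on the aggregates (binary predictor) or a
    Pearson correlation test against the phenotype (continuous). Returns
    (statistic, p_value). The predictor must be constant within individual.
    """
    x = _encode_predictor(predictor, np.asarray(gene_values).size)
    groups = np.asarray(individual_of_cell)
    labels, agg = _aggregate(gene_values, groups, aggregation)
    pheno = []
    for lab in labels:
        vals = np.unique(x[groups == lab])
        if vals.size != 1:
            raise ValueError(f"predictor varies within individual {lab!r}")
        pheno.append(float(vals[0]))
    pheno = np.asarray(pheno)

    if kind is None:
        kind = "binary" if np.unique(pheno).size == 2 else "continuous"
    if kind == "binary":
        lv = np.unique(pheno)
        a, b = agg[pheno == lv[0]], agg[pheno == lv[1]]
        if min(a.size, b.size) < 2:
            raise ValueError("Welch t-test needs >= 2 individuals per group")
        stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
    elif kind == "continuous":
        if agg.size < 3:
            raise ValueError("correlation test needs >= 3 individuals")
        stat, p = scipy.stats.pearsonr(agg, pheno)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if not np.isfinite(p):
        p = 1.0
    return float(stat), float(p)
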
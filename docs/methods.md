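# Methods

## The problem

Single-cell RNA-seq measurements are nested: cells come from individuals,
and cells from the same individual share genetic background and state, so
they are correlated. For tests of differential expression between
individuals (case vs control, or association with a donor-level trait), the
individual — not the cell — is the independent experimental unit. A power
analysis that treats every cell as a replicate overstates the evidence a
study will produce; an analysis method that does the same rejects true null
hypotheses far above its nominal level. `hierpower` quantifies both
effects: it fits a hierarchical generative model to pilot data, simulates
multi-individual single-cell counts, and estimates power and type-1 error
by Monte Carlo for three per-gene tests.

## Generative model

For each gene *i* (genes are simulated independently):

1. **Grand mean.** μ_i ~ Gamma(shape, rate), in TPM-like units.
2. **Individual means.** For individual *j*, μ_ij = max(μ_i + δ_ij, 0) with
   δ_ij ~ Normal(0, f1(μ_i)) and f1(μ) = a₁ + b₁ μ, floored at 0. The
   truncation at 0 (rather than resampling) keeps the additive-normal
   construction; its side effects are discussed under limitations.
3. **Cells.** The number of cells per individual is fixed, Poisson(λ), or
   NB(mean λ, size 1) — increasing degrees of imbalance; zero draws are
   redrawn so every individual is observed. Each cell's count is
   Y_ijk ~ NB(mean μ_ij, size f2(μ)) drawn as a gamma–Poisson mixture,
   where f2(μ) = a₂ + b₂ log μ is evaluated at the gene's (group-specific)
   grand mean and clipped into [1e-4, 1e6]; the upper cap is the Poisson
   limit.
4. **Dropout.** A per-gene rate d_i is drawn from a gamma distribution,
   rejection-sampled into [0, 1]; every cell value is independently zeroed
   with probability d_i. Observed zeros are therefore NB zeros plus dropout
   zeros, so the realized zero fraction slightly exceeds d_i.

**Binary effects.** A fold change c multiplies the grand mean of each
effect gene in one group; the direction is Bernoulli(0.5). Both f1 and f2
are evaluated at the spiked mean in the spiked group, so a spiked gene is a
fully self-consistent gene with a larger mean.

**Continuous effects.** Each individual carries a trait
P_j ~ Normal(m, s²). For an effect gene, the standardized trait and the
individual mean deviation are drawn jointly bivariate-normal with
correlation ρ (deviation scaled by √f1(μ_i)); ρ is therefore defined at
the level of the true individual means. The observable correlation between
per-individual cell averages and the trait is attenuated by within-
individual NB + dropout noise — strongly so for high-dropout genes, because
the mean signal scales with (1−d)² while the noise scales with (1−d). This
is deliberate and not corrected: it is exactly the attenuation a real study
faces.

## Estimation from pilot data

Estimation inverts the generative model from a labeled genes × cells
matrix:

- **Pruning.** Genes are visited in a seeded random order; each survivor
  removes all not-yet-visited genes with Spearman correlation > 0.25
  (midranks for ties). The surviving set contains no pair above the
  threshold, so the trend fits are not dominated by co-expressed blocks.
  The visit order's seed is recorded in the model provenance.
- **Grand means.** One cell is sampled per individual (indices shared
  across genes), the gene's non-zero sampled values are averaged, and the
  mean over 1,000 replicates is taken. Averaging non-zero values keeps the
  abundance estimate consistent with the model, where dropout is a separate
  thinning process on top of the NB counts; `nonzero_only=False` gives the
  plain mean instead.
- **Inter-individual variance.** The sample variance across individuals of
  per-individual means of non-zero values (≥ 2 qualifying individuals,
  else excluded).
- **Dispersion.** Method of moments on non-zero within-individual values:
  size = m²/(v − m) for v > m. At or below the Poisson boundary (v ≤ m)
  there is no excess dispersion; the size is capped at 1e6 and flagged.
- **Dropout.** Per-gene fraction of zero cells.

### Why the hyper-parameter fits are not plain least squares on raw points

Three small-sample effects matter at pilot scale (10 individuals, ~100
cells, ~50% dropout) and are handled explicitly:

1. **Within-sampling noise in the between-variance.** The variance of
   per-individual means estimates f1(μ) *plus* the sampling variance of
   each mean (≈ σ²_w/n per individual) — a super-linear-in-μ term that
   would tilt the f1 trend. The one-way-ANOVA moment correction (subtract
   the average estimated within-variance over n) removes it.
2. **Heavy-tailed dispersion ratios.** Per-(gene, individual) size
   estimates m²/(v−m) have a heavy right tail whenever v−m is small
   relative to its own noise. The f2 trend is therefore fitted to per-gene
   *pooled* moments, size_i = mean_j(m²)/mean_j(v−m), with a delta-method
   correction for the remaining ratio bias estimated from the
   between-individual spread, and an errors-in-variables de-attenuation of
   the slope using the estimable sampling variance of each log-mean.
3. **Low-abundance miscalibration.** Below ~20 TPM the non-zero-conditioned
   moments are intrinsically biased: non-zero counts are ≥ 1, the NB zero
   mass is non-trivial, and the truncation of individual means at 0 binds.
   Genes below this floor are excluded from the trend fits (selection on
   the regressor does not bias least squares) and the gamma distribution of
   grand means is fitted by *truncated* maximum likelihood
   (pdf(x)/sf(floor)), which identifies the full shape and rate from the
   calibrated region. If too few genes sit above the floor (data on another
   scale), the fit falls back to the plain MLE.

Both trends use two-pass weighted least squares (weights from a first OLS
pass) because the residual scale grows roughly proportionally with the
trend level; unweighted fits let the high-mean genes dominate and make the
intercepts erratic. All fits record the number of points used.

Closed-loop behavior at the reference design (5,000 genes, 10 individuals ×
100 cells): every hyper-parameter is recovered with a systematic error of
~±2%; the remaining seed-to-seed scatter is the pilot's own Monte-Carlo
noise (the f1 intercept is the most delicate, with a standard error of
roughly 1 TPM² at this scale).

## The tests

**Two-part hurdle with a per-individual random intercept** (recommended).
The detection indicator Z is modeled by logistic regression with a random
intercept per individual; the expression level of detected cells,
log(x + 1), by a linear mixed model with a random intercept. Each
component's predictor coefficient is tested by a likelihood-ratio test
(default) or Wald test; the two χ² statistics and their degrees of freedom
are summed (the components are conditionally independent), and the p-value
is the upper χ² tail. Degenerate components — all-zero gene, all cells
detected, too few detected cells — contribute statistic 0 with 0 df and are
flagged; an all-zero gene returns p = 1. On LRT failure the component falls
back to Wald and is flagged; a fully failed component marks the fit
non-converged, and power loops count such genes as non-rejections.

- The mixed *logistic* likelihood is maximized directly: adaptive
  Gauss–Hermite quadrature (25 nodes, centered per group at the posterior
  mode found by Newton's method — the integrand is strictly log-concave)
  over L-BFGS-B with the random-intercept SD bounded at 0. σ = 0 is
  accepted at the boundary and equals plain logistic regression; no
  boundary-corrected null distribution is used (plain χ² references
  throughout). The quadrature agrees with brute-force numerical integration
  of the same likelihood to ~1e-7 on small problems.
- The mixed *linear* model is maximized exactly via the 1-D profiled
  likelihood in the variance ratio (Woodbury identity per group), bracketed
  on a log grid and refined by bounded Brent. This is deterministic and
  free of the convergence failures general-purpose mixed-model optimizers
  exhibit on small, unbalanced groups; it matches `statsmodels` MixedLM
  (ML) to ~1e-8 where the latter converges.

**Naive hurdle.** The same two components with the random effects removed
(plain logistic / OLS): the cells-as-independent analysis whose operating
characteristics the package exists to expose.

**Pseudo-bulk.** Each individual is collapsed to the mean of log(x + 1)
over all its cells (configurable: log of mean, or non-zero mean), then a
Welch t-test on the aggregates (binary) or a Pearson correlation test
(continuous).

## Power engine

Power at level α is the rejection proportion among effect genes; type-1
error the same among null genes. One single-gene dataset is simulated per
Monte-Carlo draw (genes are independent in the generative model, so this is
equivalent to multi-gene datasets and embarrassingly parallel), tested, and
counted. Type-1 error runs the *identical* code path on the nullified
design (fold change 1 / ρ 0), so power at a null design equals type-1 error
by construction. Non-converged fits are tallied separately and never
counted as rejections (conservative). No multiple-testing correction is
applied: estimates are per-test at fixed α. The default of 500 genes per
estimate gives a binomial standard error ≤ 0.023.

Determinism: every stochastic stage derives its stream from one root seed
via `numpy.random.SeedSequence.spawn` in a fixed, documented order
(simulation stages: grand means, effects/phenotype, individual means, cell
counts, NB draws, dropout rates, dropout mask; power loops: one substream
per gene; grids: one substream per cell). Identical seeds give bit-identical
datasets, tables and estimates.

## Synthetic fixture truth

The default fixture model —

| parameter | value | meaning |
|---|---|---|
| grand-mean gamma | shape 1.2, rate 0.012 | right-skewed means, ~100 TPM average |
| f1 | 10 + 2 μ | between-individual SD ~15% of the mean at 100 TPM |
| f2 | 4 + 2 log μ | NB size ~13 at 100 TPM (strong overdispersion), rising slowly |
| dropout gamma | shape 8, rate 17.78 | rates centered near 0.45, SD ~0.16 |

— was chosen once to mimic the qualitative structure of published
single-cell TPM data (right-skewed means; variance growing with mean;
relative overdispersion falling with mean; roughly half the cells zero) in
a regime where the moment estimators above are informative at pilot scale:
moderate inter-individual variance so trend regressors aren't swamped by
their own noise, and overdispersion clear of the Poisson boundary so
dispersion is identifiable. These are fixture constants, not estimates of
any dataset.

What passing the closed-loop and operating-characteristic tests does *not*
show about real data: the fixture has independent genes, a single cell
type, no batch effects, exact NB within-individual noise, gene-independent
dropout, and library sizes already normalized away. Estimates on real pilot
data inherit none of these guarantees; the pruning step and the trend
floors mitigate, but cannot remove, co-expression and low-abundance
artifacts.

## Numerical choices and degenerate inputs

- NB size cap 1e6 (Poisson limit) and floor 1e-4; f1 predictions floored at
  0; dropout rates of exactly 0/1 nudged inward by 1e-6 before gamma MLE;
  dropout draws > 1 rejected and redrawn.
- Negative LRT statistics from independently optimized fits are clamped to
  0 (observed magnitudes ~1e-9).
- Spearman ties use midranks; constant genes have undefined correlation and
  are treated as uncorrelated.
- Missing values in input matrices are rejected, not imputed: the model has
  no missingness concept distinct from dropout zeros.
- Degenerate regression inputs (constant grand means, < 2 distinct x
  values, < 30 usable genes) raise with a diagnostic rather than fitting.

## Known limitations

- The truncation of individual means at 0 and the ≥ 1 discreteness of
  non-zero counts make gene-level parameters below ~10–20 TPM only weakly
  identifiable from pilot data; the estimation pipeline is calibrated above
  that floor and the gamma tail below it is inferred parametrically.
- Dropout is modeled as a gene-level, cell-independent thinning; real
  detection failure varies with cell quality and depth.
- ρ for continuous phenotypes is an individual-mean-level quantity; the
  cell-level correlation is attenuated and the package does not invert that
  attenuation.
- The mixed hurdle's χ² reference is asymptotic in the number of
  individuals; at very small J (≤ 4 per group) the LRT can drift from its
  nominal level.
- Wall-clock: a mixed-hurdle power estimate costs roughly 0.1–0.3 s per
  gene per 1,000 cells on one core; the shipped analyses use 300–500 genes
  per estimate, which puts the Monte-Carlo standard error near 0.02.
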
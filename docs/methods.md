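# Methods

`triomr` implements an integrative causal-analysis chain for a two-group
(normal-weight vs overweight/obese) multi-omics study: differential screening
of three omic layers, QTL mapping, bi-directional summary-statistic Mendelian
randomization (MR) between layers, and a network-MR mediation decomposition.
A synthetic-data generator with a fully recorded planted truth makes every
stage testable by parameter recovery. This note documents the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## Differential screens

**Expression.** Counts are normalized to log2 counts-per-million with a 0.5
pseudocount, `log2((c + 0.5) / (lib + 1) · 1e6)`; genes are kept when plain
CPM exceeds 1 in at least 25% of samples. Each gene is fit by least squares
on `[intercept, group, covariates]` (the exercise covariate is always
included). Residual variances are moderated by an empirical-Bayes prior: with
per-gene residual variance s²_g on d degrees of freedom, the prior (d0, s0²)
is estimated by method of moments on log s²_g — the excess variance of
`log s²_g − ψ(d/2) + log(d/2)` over the theoretical trigamma term is inverted
through a Newton iteration on the trigamma function — and the posterior
variance is `s̃²_g = (d0 s0² + d s²_g)/(d0 + d)`. The moderated t uses
`d0 + d` degrees of freedom; p-values are BH-adjusted. When the log-variances
have no excess spread the prior degrees of freedom are infinite and the prior
variance is set to the geometric mean of the gene variances, so moderation
exactly reproduces the common value. The `d0 → 0` limit reproduces the
ordinary t-statistic; `d0 → ∞` gives a pooled-variance z-statistic. The
estimator is cross-checked in the test suite against an independently coded
moments oracle (Brent inversion) and against Bioconductor limma.

Significant genes require adjusted p ≤ 0.01 **and** |log2FC| ≥ 5 (both
inclusive). The fold-change base is log2, so the threshold means 32-fold; the
screen is intentionally extreme and the generator plants contrasts of that
size.

**Co-expression hubs.** Significant genes enter a greedy planar-filtered
network: gene pairs ranked by |Pearson r| (lexicographic tie-break) are
inserted while the graph remains planar, up to the planar bound of 3n − 6
edges; hubs are nodes whose degree exceeds the 90th percentile of the degree
distribution, falling back to maximal-degree nodes when the strict cut would
exclude everything (small, near-regular networks). This is a deliberately
simplified stand-in for multiscale embedded co-expression analysis: the
planar filter is the same first step, and degree is a first-order proxy for
multiscale hubness. Inside the pipeline the correlation matrix is computed on
group- and covariate-residualized expression, because a 32-fold group
contrast otherwise dominates every pairwise correlation and hub identity
becomes arbitrary; adjusting co-expression input for known structure is
standard practice.

**Methylation.** Each site is modeled as a per-sample binomial:
methylated counts out of coverage, logit-linked, with `group + covariates`
as predictors. The fit is an iteratively reweighted least-squares GLM
vectorized across all sites (batched 3×3 solves), with the group term tested
by likelihood ratio against the reduced model. Zero-coverage cells carry
zero weight; sites need at least 3 covered samples per group. Separation is
handled by clamping coefficients at ±15 with a flag; non-converged fits
report p = NaN. Per-site statistics are validated against statsmodels GLM
fits to 1e-6. PMD (percent methylation difference) is 100 × (mean case
proportion − mean control proportion) over covered samples. FDR q-values use
BH by default with Storey's π₀ rescaling as an option (the sliding-linear-
model q-value variant is not reimplemented; BH is the conservative standard
substitute). Significant sites require q < 0.01 and |PMD| > 10 (strict), or
|PMD| > 15 for the stringent set that feeds MR; the absolute value matters
because hypo-methylated sites carry negative PMD. Sites map to genes by
minimal distance to the transcription start site, ties broken toward the
smaller TSS coordinate then lexicographic gene id.

**Metabolites.** Abundances are log-transformed and autoscaled. PLS-DA is fit
by NIPALS against the centered 0/1 group label (default 2 components — the
usual metabolomics choice; the component count is configurable and must stay
below the matrix rank). VIP scores follow
`VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a)`, so the mean squared
VIP is exactly 1. In parallel each metabolite enters a logistic regression of
group on scaled abundance plus covariates (statsmodels GLM); significance
requires VIP > 1 and Wald p < 0.05, both strict.

## QTL mapping

Every (variant, feature) pair is tested under an additive dosage model.
Features are first moved to an unbounded scale: log2-CPM expression, logit
methylation proportion with 0.5-count smoothing, log metabolite abundance.
Both feature and dosage are residualized on the covariates plus intercept,
then the scan reduces to matrix cross-products; by Frisch–Waugh this is
identical (verified to 1e-8) to per-pair OLS with covariates included
directly. Degrees of freedom are n − 2 − n_covariates. Monomorphic variants
yield flagged records with missing p; exact fits floor the p-value at 1e-300
and are flagged. Significant QTLs require p < 1e-5, strict.

The scan covariates default to **group and exercise**. Including the
phenotype group is a deliberate choice: the biomarkers entering QTL analysis
are group-selected and strongly group-shifted, and group is a common cause of
features in all three layers, so conditioning removes a large non-genetic
variance component and the main cross-layer confounder. Scanning without
group is one config entry away.

## Mendelian randomization

Instrument sets are built from exposure QTLs at p < 1e-5. Outcome statistics
are looked up by variant; a missing variant is replaced by the highest-r²
proxy with r² strictly above 0.8, its effect sign aligned with the dosage
correlation sign. Instruments are greedily LD-pruned at r² > 0.1 (keep the
smallest-p member of each clump); pruning is configurable including "off".
Per-instrument Wald ratios use the first-order standard error
se_out/|β_exp| by default (second-order delta-method optional). An empty set
marks the pair untestable rather than raising.

Estimators, each validated against an independent formula-level oracle:

* **IVW** — fixed-effect inverse-variance weighting, identical to weighted
  least squares of outcome betas on exposure betas through the origin;
  optional multiplicative random-effects scaling.
* **Simple and weighted median** — interpolated (weighted) 50th percentile of
  the ratios with cumulative-midpoint interpolation; standard errors from a
  parametric bootstrap (default 1000 draws) of the per-instrument normal
  fits.
* **MR-Egger** — weighted regression with a free intercept after orienting
  exposure betas positive; the intercept and its normal-theory p form the
  directional-pleiotropy test. A 2-instrument fit is exact and flagged
  "saturated"; saturated fits are excluded from evidence counting.
* **MR-PRESSO-style residual-sum test** — observed RSS of leave-one-out IVW
  predictions compared against parametric simulations (default 1000) drawn
  from the per-instrument fits; per-instrument terms give Bonferroni-
  corrected outlier flags and the corrected estimate is IVW after outlier
  removal. The distortion test is out of scope.

All estimators sort instruments by variant id before consuming the seed, so
results are invariant to row order. Confidence intervals are
estimate ± 1.959964·se; p-values two-sided normal.

A pair direction is **significant** when at least two counted methods (IVW,
simple median, weighted median, Egger slope) reach p < 0.01, **suggestive**
when at least two reach p < 0.05, applying the same two-method counting rule
to both tiers. The direction call is forward/reverse when only one direction
reaches at least suggestive (an untestable direction counts as null),
bidirectional when both do.

This is a one-sample design analyzed with two-sample summary-statistic
estimators, mirroring the study layout it reproduces. One-sample MR with
summary statistics carries weak-instrument bias toward the observational
association, and reverse-direction tests can pick up instruments of the true
exposure when those reach the outcome's QTL threshold; both effects are
visible in the recovery experiments below and bound the achievable
direction-call accuracy.

## Network-MR mediation

For an X → M → Y triple the total effect τ (IVW of X on Y) decomposes into
the indirect effect β₁β₂ (product of the X → M and M → Y IVW estimates, se by
the delta method `sqrt(β₁²se₂² + β₂²se₁²)`) and the direct effect
τ − β₁β₂, so total = direct + indirect holds exactly by construction.
The default mediation test is a one-sided normal p on |indirect|/se; a
two-sided Sobel test and a total-vs-indirect difference test are selectable.
The one-sided default was chosen because it reproduces the reporting
convention of the study design this package mirrors; the difference test is
retained because the verbal description of the procedure ("difference
between indirect and total effect") points at it, and the two readings
cannot be reconciled — the report records which test produced each p-value.
Triples are enumerated over the three cross-layer pathway classes
(metabolite→gene→site, metabolite→site→gene, gene→metabolite→site); by
default all class triples over the selected biomarkers are tested, with an
optional gated mode that requires forward pair calls on both steps.

## Synthetic data generator

Genotypes are biallelic SNPs in Hardy–Weinberg equilibrium: dosages are sums
of two independent haplotypes, each a thresholded latent Gaussian. Within an
LD block the latent process is AR(1) and the per-step latent correlation is
solved numerically (bivariate-normal orthant probability, Brent's method) so
the **dosage** correlation matches the configured target — thresholding
attenuates correlation, and two binary alleles can only correlate strongly
when their frequencies match, so block members share an allele frequency.
Blocks never span chromosomes and are mutually independent.

Each feature's latent signal is the sum of calibrated QTL dosage effects,
causal-edge contributions from upstream features (topological order; edges
propagate the base-free signal), group and covariate effects, and Gaussian
noise (sd 0.3 expression / 0.3 methylation / 0.35 metabolite). Observation
models: Poisson counts of exp(latent) for expression (log-mean base 6 ≈ 400
reads); Binomial(coverage, expit(latent)) methylation with coverage
1 + Poisson(29) (mean 30 — typical reduced-representation bisulfite depth);
exp(latent) metabolite abundances. Everything is a pure function of
(config, seed).

The default scenario mirrors the study scale: 104 samples in two groups of
52, one binary exercise covariate with group-dependent prevalence (85% vs
67%), 60 genes / 40 CpG sites / 30 metabolites, 120 SNPs in LD blocks of 4.
Planted structure: 10 genes at ±4 natural-log group contrast (≈ ±5.8 log2,
baselines offset by half the contrast so library sizes stay comparable), 6
sites at ±1.2 logit, 8 metabolites at ±1.2 log; three calibrated instruments
per biomarker (per-allele β = 1.0, methylation 0.9, rescaled to each
variant's realized dosage variance so every instrument carries a comparable
partial R², which is what the p < 1e-5 selection rule demands at n = 104);
and one causal chain metabolite → gene → methylation with b₁ = b₂ = 0.6.
The chain's source metabolite gets stronger instruments (×1.4), the mediator
gene fewer-but-stronger ones (×1.5), and the outcome site only weak
sub-threshold meQTLs (β = 0.3): at this sample size an outcome's own strong
instruments would dominate its variance — destroying forward-MR power while
serving only the reverse test — whereas single CpGs without strong meQTLs
are the common case. The mediator gene also drives a seven-gene
co-expression module (β = 1) so it surfaces as the network hub. Group
effects planted on chain/module members are compensated for what they
inherit through edges, so the realized contrast equals the configured value.

## What the experiments show — and what they do not

Measured by `scripts/acceptance.py` (problem sizes chosen to keep the whole
run in tens of seconds): the planted chain is called forward in ≈ 85–95% of
replicates and declared as mediation in ≈ 95–100%, with the mean indirect
estimate within a few percent of b₁b₂; planted QTL effects are covered by
95% CIs at ≈ 94–96% over 200 replicates; IVW rejects at ≈ 5% under the null;
null scan p-values are uniform; the residual-sum outlier test flags a
10-ratio-se outlier essentially always. The weighted median stays nearly
unbiased under 40% balanced pleiotropy, but its parametric-bootstrap se —
built from the reported per-instrument standard errors, which know nothing
of pleiotropy — understates the contaminated-replicate dispersion, so its
2-se coverage sits near 0.8 where IVW's collapses below 0.45; robustness of
the median is a statement about the point estimate, not about its nominal
interval.

The generator emulates linear-on-latent-scale effects, balanced groups,
independent LD blocks and instrument sets disjoint across biomarkers. It does
not emulate population structure, genome-wide LD, negative-binomial
overdispersion beyond the Poisson option, cell-type composition, batch
effects, or assay missingness — passing tests show the chain of methods is
implemented correctly and calibrated under its own assumptions, not that
those assumptions hold in any real cohort.

## Numerical choices

* p-value floor 1e-300 in QTL scans; exact fits flagged "degenerate".
* Logistic/binomial fits clamp coefficients at ±15 (flagged) and report
  missing p on non-convergence or separation.
* Methylation logit smoothing (m + 0.5)/(cov + 1) keeps transforms finite at
  0% and 100% methylation.
* Greedy planarity testing uses the standard left-right planarity check; the
  insertion loop stops at the 3n − 6 planar edge bound.
* Bootstrap and simulation draws always follow a variant-id sort, making
  every MR result order-invariant for a fixed seed.
* Trigamma inversion by Newton iteration with series endpoints for extreme
  arguments; validated by round-trip property tests.
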
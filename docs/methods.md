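# Methods

## Statistical model

### Design and contrasts

The experiment crosses diagnosis (CTRL/SZ) with treatment (VEH/JQ1). The
two factors are combined into one four-level group variable and fitted
with cell-means coding (no intercept), so every printed comparison is a
single contrast of group means:

| contrast | weights over (CTRL_VEH, SZ_VEH, CTRL_JQ, SZ_JQ) |
|---|---|
| `SZ_vs_CTRL` | (−1, 1, 0, 0) |
| `JQ_vs_CTRL` | (−1, 0, 1, 0) |
| `SZJQ_vs_CTRL` | (−1, 0, 0, 1) |
| `ADDITIVE` | (−2, 1, 1, 0) |
| `SYNERGY` | (1, −1, −1, 1) |

`ADDITIVE` is the sum of the two single-perturbation contrasts and
`SYNERGY` is the classical interaction contrast; by linearity
`S_g = C_g − A_g` holds exactly for the fitted coefficients, and the test
suite asserts it at 1e-10.

### Precision weights and moderation

Counts are filtered (strictly more than `min_count = 15` in at least
`min_samples = 2` samples; the inclusive variant is available via
`strict=False`), scaled by TMM factors (trim fractions 0.3 on M and 0.05
on A per tail, inverse asymptotic-variance weights, reference sample by
the upper-quartile rule, factors rescaled to geometric mean 1 — verified
against the canonical implementation to machine precision), and converted
to `log2((count + 0.5) / (eff_libsize + 1) × 1e6)`.

Per-observation precision weights follow the voom recipe: square-root
residual standard deviations from unweighted gene-wise fits are smoothed
against average log2 count by lowess (span 0.5), each fitted log2 count is
mapped through the trend with end clamping, and the weight is the fourth
inverse power of the interpolated value.

Residual variances are shrunk toward a scaled-F prior `(d0, s0²)`
estimated by closed-form moment matching of log variances
(digamma/trigamma inversion; agreement with the reference empirical-Bayes
implementation to 1e-6). Moderated t statistics use
`s̃²_g = (d0·s0² + d·s²_g)/(d0 + d)` on `d0 + d` degrees of freedom, with
two-sided p-values and BH adjustment. No variance trend and no robust
down-weighting is applied in the moderation step (the simplest published
variant); `d0` and `s0²` can be forced for the two limiting cases
(ordinary t at `d0 = 0`, full shrinkage at `d0 = ∞`).

### Synergy classification

The global threshold τ is the scalar mean over genes of the moderated
SE of the `SYNERGY` contrast (a per-gene-SE variant is exposed via
`per_gene=True`). A gene is *positive synergy* when `S_g > τ`, *negative
synergy* when `S_g < −τ`. The call is promoted to `more_up`
(resp. `more_down`) only when the additive prediction shows the same or no
direction, implemented as `A_g ≥ 0` (resp. `A_g ≤ 0`).

This strict sign clause deserves a caveat. For a gene whose true effect is
pure interaction, the true additive effect is zero, so the *estimated*
`A_g` is zero-mean noise and its sign is a coin flip: the clause vetoes
about half of genuine interaction genes (sensitivity ≈ 0.5 in planted-gene
simulations) while suppressing false calls very effectively (≈ 1–2% of
null genes leave `as_predicted`, helped by the negative sampling
correlation between the `ADDITIVE` and `SYNERGY` estimates under this
design). A widened "no direction" zone — `direction_zone > 0` treats
`|A_g|` below that width as directionless — raises sensitivity to ≈ 0.8
at the cost of ≈ 12% null leakage. No zone width achieves both high
sensitivity and low leakage at n = 14 samples; the default is the strict
rule, and the trade-off is the user's.

Heatmap support clusters rows and columns with Euclidean distance and
complete linkage, pre-aggregating rows by k-means (k = 100, fixed seed)
when more than 1000 rows are clustered.

### Enrichment

The competitive test converts moderated t statistics to normal-equivalent
scores and compares in-set vs out-of-set means with a two-sample statistic
whose in-set variance is inflated by `VIF = 1 + (m − 1)·ρ̄`, on G − 2
degrees of freedom. ρ̄ defaults to 0.01 and can be estimated per set from
a residual matrix. Over-representation uses the exact upper-tail
hypergeometric probability against the expressed-gene universe; a hit
outside the universe is an error, never a silent drop. BH adjustment is
applied across all sets tested in one run.

### Co-expression modules

Unsigned adjacency `|cor|^β` with β = 7; topological overlap
`TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij)`;
average-linkage clustering of 1 − TOM. Module calling uses a *static* cut
of the dendrogram at dissimilarity 0.98 rather than the dynamic tree cut:
under a power-7 unsigned network, clusters of unrelated genes only
assemble in the last few thousandths of the dissimilarity scale, while
genuinely co-expressed blocks complete well below it, so a fixed
near-ceiling cut separates the two regimes. Clusters below 30 genes fall
into the reserved "grey" module.

Because hierarchical clustering chains a few weakly attached genes into
any large branch, assignments are then cleaned by eigengene membership
(kME): members whose |kME| is not significant at p = 0.005 (Student test,
n − 2 df) are demoted to grey and grey genes significant at p = 0.001 are
rescued, iterating to a fixed point, with each module's eigengene anchored
on its 30 most central members so that weak joiners cannot tilt it toward
themselves. Both thresholds are significance levels, so they adapt to the
sample count.

Module eigengenes are unit-norm leading principal-component score
vectors of the standardized in-module expression, sign-aligned with the
module's mean profile. Modules whose eigengene dissimilarity `1 − cor`
falls below 0.17 are merged iteratively (closest pair first, larger
module's label kept). Module–trait association is weighted Pearson
correlation (uniform weights by default, reducing to ordinary Pearson)
with the Student asymptotic p-value on n − 2 df. Covariate
residualization of the input expression is left to the caller; the
module pipeline consumes any genes × samples matrix.

### Promoter co-occupancy

Promoters are `[tss − 1000, tss + 1000)` windows (0-based half-open,
clamped at zero; symmetric, so strand only annotates). RPKM is
`count × 1e9 / (length_bp × libsize)`. Signals are compared by Spearman
correlation with midranks for ties and the large-sample t approximation.
Upstream alignment and peak calling are consumed, not performed.

## Synthetic data

The generator emulates the study design: four groups of 4/3/4/3 samples,
log-normal library sizes (log-mean ln 1e7, log-sd 0.3), per-gene
natural-log baselines N(4, 2²) converted to library proportions, and
negative-binomial counts with a decreasing dispersion trend
`φ(μ) = 0.05 + 2/μ` (biological coefficient of variation ≈ 22% for
abundant genes, rising at low counts — typical of bulk RNA-seq).
Diagnosis, treatment, and interaction effects are independent Bernoulli
draws (defaults 10%/10%/5% of genes) with log2 magnitudes |N(1.5, 0.3²)|
and random signs; genes carrying several effects are labeled "mixed" so
the classifier's direction logic is exercised.

Correlated blocks for module testing share a per-sample latent factor on
the log2 scale whose variance fraction equals `block_cor`. Three
deliberate departures from naive sampling keep the generator faithful to
its own contract at n = 14 samples: realized factor draws are
standardized (otherwise the realized shared variance is chi-squared-noisy
and the attained correlation can fall far from `block_cor`), factors of
distinct blocks are orthogonalized (planted blocks are *exactly*
uncorrelated), and block baselines are drawn from the mid-range of the
abundance distribution — low-count blocks would drown the factor in
sampling noise, while blocks in the extreme-abundance tail would couple
every other gene to the factor through library-size closure
(compositional leakage). The factor amplitude (1.5 log2 units) keeps
counting-noise attenuation of the correlation below a few percent.

Gene-set collections sample uniformly without replacement; enriched sets
oversample a ground-truth class with a configurable odds ratio (default
10), and category labels cycle through eight neural-themed categories.
Paired promoter-occupancy tables derive both signals from a shared
standard-normal latent with independent noise, mixed via
`r = 2 sin(π ρ_s / 6)` so the count-scale Spearman correlation lands on
the requested target; counts are a deterministic log-normal transform, so
`target_rho = 1` yields exactly tied ranks.

What the generator does **not** model: batch effects beyond library size,
gene length (counts are proportion-based), UMI/single-cell zero
inflation, outlier samples, and correlated *null* structure outside the
planted blocks. Passing tests therefore demonstrate correctness of the
statistical machinery under a well-specified NB world, not robustness to
every artifact of real data.

## Numerical choices and degenerate inputs

- TMM pairs exclude genes with a zero count in either sample; a sample
  with zero total is an error.
- The mean-variance trend interpolates piecewise-linearly and clamps at
  its end points; weights are floored at trend value 1e-6 to avoid
  division blow-ups.
- Prior estimation excludes non-positive residual variances and returns
  `d0 = ∞` when the observed log-variance spread is within the residual
  chi-squared expectation.
- A single-gene module's eigengene is the standardized gene itself;
  constant expression rows are rejected wherever a correlation is needed.
- BH uses the step-up construction with explicit monotonicity enforcement
  and capping at 1; ties in ranks use stable sorting.

## Problem sizes

Simulation-based checks run at 2,000 genes × 14 samples (calibration and
planted-effect recovery, 10–20 replicates), 500 genes for module
recovery (3 replicates, median ARI reported), 1,000 permutations for
enrichment calibration, and 5,000 regions for co-occupancy calibration —
sizes at which the Monte-Carlo error of each reported quantity is small
relative to its acceptance band.

## Known limitations

- The dynamic tree cut proper (branch-shape-aware) is not implemented;
  the static cut plus kME refinement recovers planted blocks well but may
  split or blur fine nested module structure on real data.
- With 14 samples, gene-level correlation estimates have a standard error
  near 0.27; a few percent of unrelated genes are statistically
  indistinguishable from weak module members, bounding achievable module
  purity regardless of algorithm.
- The strict direction clause halves sensitivity for pure-interaction
  genes (see above); this is a property of the published classification
  rule, not of the estimator.
- camera-style enrichment uses a fixed or residual-estimated scalar ρ̄ per
  set; rotation- or permutation-based null distributions are out of scope.
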
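# Methods

## Model overview

`methylsignal` treats differential methylation as a signal-detection
problem. At a cytosine with `n_meth` methylated and `n_unmeth`
unmethylated reads, the methylation state is a Bernoulli distribution
with level `p = (n_meth + a)/(n_meth + n_unmeth + a + b)`; the Jeffreys
prior `(a, b) = (0.5, 0.5)` is applied only when converting counts to
levels (never stored), so low-coverage sites cannot produce degenerate
levels of exactly 0 or 1. The divergence between a sample and the
reference at one site is the squared Hellinger divergence

    H(p, q) = (√p − √q)² + (√(1−p) − √(1−q))²  ∈ [0, 2],

reported unweighted (`hdiv`) and weighted by the harmonic-mean coverage
`w = 2·n_ref·n_smp/(n_ref + n_smp)` (`hdiv_w`, the default for
modeling — it carries read-depth information, shrinking the divergence
of poorly covered sites), together with the total-variation distance
`tv = |p − q|`. All three are symmetric and zero iff the levels agree.

### Reference methylome and leave-one-out controls

The reference is the centroid of the control group: element-wise count
sums over the union of site keys. Summing counts (rather than averaging
proportions) makes the reference level the coverage-weighted mean of the
control levels and preserves depth for the weighted divergence. At least
three control replicates are required (configurable to a warning),
because background stochastic variation cannot be estimated from fewer.

Controls are themselves scored against the reference — their divergences
are the empirical null used for cutoff learning. Each control is
compared against the pool *minus its own counts* (leave-one-out,
`loo_controls=True`). Comparing a replicate against a pool containing
its own reads shrinks its divergence roughly in proportion to its share
of the pool; with 3 controls this made control divergences about half
the treatment divergences on zero-effect simulations and turned the
learned cutoff into a systematic treatment-DMP generator (raw type-I
fraction ≈ 0.48 instead of 0.05). With leave-one-out the two groups are
exchangeable under the null. The self-inclusive variant remains
available (`loo_controls=False`), and a single-control pool falls back
to self-comparison.

### Divergence distribution model

Positive divergences of one sample × context are modeled with the
generalized gamma family

    f(x; α, ψ, δ) = δ/(ψ Γ(α)) (x/ψ)^(αδ−1) exp(−(x/ψ)^δ),  x > 0,

which nests the two-parameter gamma (δ = 1), Weibull (α = 1) and
exponential (α = δ = 1). Zeros are excluded (and counted): the model
describes positive divergence, and an atom at zero breaks the MLE.
Fitting is maximum likelihood over log-parameters (Nelder–Mead followed
by an L-BFGS-B polish), started from method-of-moments gamma estimates
with δ = 1, with up to 3 seeded jittered restarts — deterministic given
the data. By default all three family members are fitted and the lowest
AIC wins, ties toward fewer parameters. AIC and the Kolmogorov–Smirnov
statistic are reported as diagnostics but never gate the pipeline.
Quantiles come from the exact inverse incomplete-gamma form. Fits are
per sample × context; contexts are never pooled, since CG, CHG and CHH
methylation behave differently in plants.

### Potential DMPs and the learned cutoff

Sites whose divergence exceeds the fitted distribution's 95th percentile
(configurable) are potential DMPs, for controls and treatments alike.
Each candidate is then expressed on its own replicate's distribution
scale — divergence divided by that sample × context's fitted
95th-percentile quantile (`cutoff_scale="relative"`). This makes
candidates comparable across replicates regardless of coverage: under
leave-one-out the reference pool behind a control has the depth of 2
replicates versus 3 for a treatment sample, which inflates raw weighted
divergences of treatments by ~10–12% and would bias any shared absolute
cutoff. The classification cutoff separating control from treatment
candidates is learned per context by an exhaustive sweep over every
observed value (rule: value ≥ cutoff → treatment), maximizing the Youden
index J = sensitivity + specificity − 1 (accuracy available); ties break
toward the smallest cutoff, and all five metrics (accuracy, sensitivity,
specificity, FDR, Youden) are reported at the optimum. The learner is a
deterministic 1-D optimal-threshold rule — the minimal classifier for a
monotone score — with a hook for alternative scorers. One cutoff is
learned per context across all replicates. If one candidate class is
empty the pipeline logs a warning and falls back to the percentile
threshold alone. Treatment *and* control replicates receive DMP calls
(control calls feed the gene-level group comparison); each DMP carries a
hypo/hyper direction (sign of `p_smp − p_ref`), and both directions are
retained equally.

### Gene-level calling

DMPs are counted inside annotated genes (1-based inclusive overlap,
strand ignored; a DMP in two overlapping genes counts for both; all
genes appear, zeros included). Genes with at least `min_dmps = 3` pooled
treatment DMPs and a density of at least `min_density = 3` per 10 kbp
are tested: intercept-only vs group-effect models under Poisson (closed
form — group MLEs are the group means) and, when the pooled sample
variance exceeds the mean, also under an ML-fitted NB2 negative binomial
(statsmodels); the family with the lower group-model AIC supplies the
likelihood-ratio statistic, referred to χ²(1). `log2fc` compares group
mean DMP counts (+∞ when the control mean is zero and the treatment mean
positive). Benjamini–Hochberg adjustment across tested genes and the
gates `p_adj < 0.05`, `log2fc > 1` (one-sided by default, two-sided
available) flag DMGs.

The χ²(1) reference for the LRT is anti-conservative at very small
counts: on exact Poisson null data the p < 0.05 fraction is ≈ 0.09 at
mean 0.8 and ≈ 0.06 at mean 1.7, converging to 0.05 by mean ≈ 3.5.
Calibration checks therefore evaluate genes whose total DMP count is
≥ 18 across 6 replicates (mean ≥ 3); under the null the total is
independent of the group split, so this restriction does not bias the
check. This small-count behavior is a known limitation for sparse genes.

## The baseline pipeline

The comparison pipeline is the prevalent archetype: replicate counts are
pooled within group (such methods require only two samples); each shared
site passing coverage in both pools gets a two-sided Fisher exact test
(two-sided by the "sum of table probabilities ≤ observed" convention —
conventions differ between tools); BH-adjusted p < 0.05 AND an absolute
pooled-level difference ≥ 20% (the conventional cutoff; the boundary is
inclusive, with a 1e-12 float tolerance) define baseline DMPs; DMPs are
binned into fixed non-overlapping 100-bp tiles, and tiles holding ≥ 3
DMPs (optionally direction-uniform) are DMRs; a gene is a baseline DMG
iff it intersects ≥ 1 DMR. Sliding windows and the regression variants
are intentionally out of scope.

## Downstream analysis

Term enrichment uses the hypergeometric upper tail: for a term with K
annotated genes among N population genes and k hits among n study genes,
fold = (k/n)/(K/N) and p = P(X ≥ k); results are BH-adjusted and
filtered to fold > `min_fold` (default 4). Unannotated genes count in N
only.

Network hubs: the user-supplied edge list (STRING-export-like TSV) is
loaded as a simple undirected graph (self-loops dropped); nodes with
fewer than 2 edges are removed in a single pass (cascading removal
optional, off by default — survivors whose degree fell below the bar are
kept). Six per-node metrics are computed with connectivity handled per
component: unnormalized betweenness (pair-summed, endpoints excluded),
closeness `(n_comp−1)/Σd`, average shortest path length `Σd/(n_comp−1)`,
local clustering coefficient, degree, and eccentricity; isolated nodes
get 0 for the distance-based metrics by convention. Both closeness and
average path length are kept as separate k-means features even though
they are reciprocally related, matching the six-metric convention of the
workflow this reproduces. Profiles are z-scored per metric before
clustering — the metrics live on wildly different scales and raw
Euclidean distance would be degree-dominated. k-means is Lloyd's
algorithm (k = 3, ≤ 500 iterations by default) with a seeded
kmeans++-style start (k distinct data points, successive picks weighted
by squared distance — plain uniform starts visibly converge to bad local
optima on separated clouds); everything is deterministic given the seed.
The *core hub* is the cluster with the highest mean standardized
degree + betweenness (any single metric selectable), mirroring
"highest centrality" operationalized through connectivity scores.

## The synthetic-data generator

`simulate_experiment` emulates the statistical structure of a plant WGBS
experiment rather than reads:

- **Genome.** Default one 200-kbp chromosome, 100 non-overlapping genes
  of 1–2 kbp laid out with even gaps, 10,000 cytosines (1 per 20 bp) at
  60% CHH / 25% CG / 15% CHG — desk-scale by construction; all sizes
  configurable.
- **Baseline levels** per context are beta mixtures: CG bimodal with
  mass near 0 and near 1 (0.6·Beta(1,10) + 0.4·Beta(10,1),
  gene-body-like); CHG intermediate-low (Beta(1.5,5)); CHH low
  (Beta(1,12)).
- **Epimutation noise.** Independently per replicate — in both groups —
  each site's level is redrawn from its context distribution with
  probability 0.02. This models replicate-level stochastic variation as
  a level-redraw process, not a transgenerational inheritance model: the
  operational property that matters is noise present identically in both
  groups, signal only in treatment. The rate is a package default chosen
  to make replicate noise visible above binomial sampling at 20×
  coverage.
- **Signal.** A drawn subset of genes (default 20) shifts its sites'
  treatment-group levels by ±0.4 (hyper/hypo 50:50 per gene, clamped to
  [0,1]). A per-class site fraction (< 1 for sparse signal) and
  additional `(n_genes, effect, site_fraction)` classes allow
  mixed-density designs in a single experiment.
- **Counts.** Coverage is negative binomial (mean 20, dispersion 5,
  WGBS-like depth variability); methylated counts are binomial in the
  replicate's level. Everything derives from one seed; identical seeds
  give identical files.

What the generator does *not* emulate: linkage/autocorrelation of
methylation along the chromosome (relevant to smoothing-based callers,
which are out of scope), bisulfite conversion error, context-dependent
coverage, or correlated epimutation between neighboring sites. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated noise model, not performance on every property of real
methylomes.

## Verification runs and problem sizes

The acceptance checks (tests and `scripts/acceptance.py`) use:
planted-signal recovery on the default genome (20 genes at effect 0.4,
3v3, coverage 20 — expected ≥ 90% sensitivity with ≤ 10% false calls);
zero-effect calibration on a 2-Mbp genome with 500 genes of 2–4 kbp and
100,000 sites (genes long enough to put DMP counts in the χ²-calibrated
regime, see above); distribution-fit recovery on 20 replicates of 5,000
generalized-gamma draws (α=1.5, ψ=0.8, δ=1.2; median relative error
< 10% per parameter, typically ≈ 5%); and a mixed-density comparison on
the default genome with 8 sparse-strong (effect 0.45 at 30% of sites),
4 dense-strong and 8 dense-weak (effect 0.20, the baseline's own
difference cutoff) genes, where the two pipelines disagree in both
directions. Brute-force oracles (exhaustive cutoff sweep, hypergeometric
enumeration of Fisher tables, step-up BH, all-pairs shortest-path
centralities) back the unit-level checks.

## Known limitations

- The LRT χ²(1) reference is anti-conservative for genes with very few
  DMPs (documented above); a parametric-bootstrap reference would fix
  this at significant cost.
- The learned cutoff under a pure null is arbitrary (any threshold is as
  good as any other); downstream results remain protected by the
  gene-level group test and BH adjustment, but DMP counts themselves are
  not interpretable without treatment signal.
- Planted hypo-methylation effects are truncated by the [0,1] clamp at
  sites with low baseline levels (most CHH sites), so hypo-direction
  signal genes carry genuinely less signal than hyper-direction ones and
  recovery varies by a few genes across simulation seeds.
- Exon- and TE-level features, beta-binomial/logistic baselines,
  smoothing kernels and sliding-window DMRs are intentionally not
  implemented.
- With `loo_controls=False` (self-inclusive comparison) the null is
  visibly anti-conservative; the option exists for fidelity to
  centroid-only workflows, not for inference.
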
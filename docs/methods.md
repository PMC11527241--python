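# Methods

This note documents the statistical procedures gliastate implements, the
assumptions baked into each, the synthetic-data model used to exercise
them, and the design choices made where several readings were defensible.

## Mixing entropy

For integrated cluster *i* with `N_i` cells and composition `p_ij` over
the K batch (or sample) categories present globally,

    H(i) = -Σ_j p_ij log2 p_ij        (bits; 0·log 0 ≡ 0)
    H    =  Σ_i H(i) · N_i / N        (cell-count-weighted overall)

Both are normalized by `log2 K`, the maximum achievable entropy, giving
values in [0, 1]: 1 when every category appears at its global frequency
in each cluster, 0 for single-category clusters. The report also surfaces
the *inner sum* `Σ_j p_ij log2 p_ij` (≤ 0) and the uniform-distribution
constant `-log2 K`, because normalization constants are conventionally
quoted on that negative scale (4 categories → −2 bits; 490 → −8.9).
When K = 1 the maximum entropy is 0 and the normalized value is defined
as 0 with a warning rather than dividing by zero. Entropy is invariant
to relabeling of categories and clusters; the overall value equals the
`N_i/N`-weighted mean of the per-cluster values to 1e−9 (property-tested).

Cells missing a cluster or grouping label are dropped with a logged
count. Samples contributing fewer than 10 cells are removed before any
metric (inclusive boundary: exactly 10 cells is kept).

## Label–cluster NPMI

With empirical joint `p(x,y)` of original state label x and integrated
cluster y,

    pmi(x;y)  = log2 [ p(x,y) / (p(x) p(y)) ]
    npmi(x;y) = pmi(x;y) / (−log2 p(x,y))  ∈ [−1, 1]

Conventions: `p(x,y) = 0` ⇒ npmi = −1 (never co-occur); `p(x,y) = 1` ⇒
npmi = +1 (degenerate perfect association). Labels or clusters with zero
marginal are excluded with a log entry. The full matrix is always
emitted; as a scalar summary we report the `p(x,y)`-weighted mean of the
matrix — a standard mutual-information-style reduction, chosen here
because no canonical scalar exists for NPMI matrices. Per-cohort
matrices are available via `by_cohort=True`.

## Differential proportion analysis

Per donor, `proportion(sample, cluster)` = nuclei of that donor in the
cluster / the donor's total nuclei, so each donor's proportions sum
to 1 (the alternative reading — a per-cluster denominator — is not a
proportion and would not admit a stacked-bar visualization). Clusters a
donor lacks enter as exact zeros; the cube root of 0 is 0.

Per cluster and per pairwise contrast (Control as reference; one
non-control group at a time), an ordinary least squares fit of

    proportion^(1/3) ~ intercept + sex + 1[group = case]

with Gaussian errors and identity link. This matches a generic `glm`
Gaussian fit, including t-based two-sided p-values. Rank-deficient
designs (e.g. sex perfectly confounded with group) raise an error naming
the collinear columns rather than silently pseudo-inverting. No
multiple-testing correction is applied by default; a Benjamini–Hochberg
flag adds q-values across clusters. Samples without covariate
information are removed with a logged count. Group-average composition
tables are unweighted means of per-donor proportions, so each group's
means again sum to 1.

The cube-root transform stabilizes the variance of small compositional
shares and linearizes the generator's injected effects (below), but the
fitted beta is *not* exactly the injected effect: cubing and
renormalizing shrink the observed cube-root scale slightly, by an amount
that grows with the affected cluster's baseline share. At the default
baseline (2% activated) the shrinkage is ≈ 6% of the effect.

## Spatial quantification

* **Layer I** is excluded up front (sparse capture), with a logged count.
* **Top-quantile selection**: within each sample, a spot is in-state iff
  its score ≥ the nearest-rank-higher (1−q)-quantile of that state's
  scores — the value at 1-based rank `floor((1−q)·n) + 1`. Ties at the
  threshold are all included, so between `ceil(q·n)` and `n` spots are
  selected and the rule is deterministic and order-independent.
  Thresholds are per state within each sample (per-level thresholds
  would make between-level comparisons circular); with multiple slides,
  thresholds are per slide.
* **Proximity**: the operative definition is the direct-overlap
  annotation (proximal = overlapping a plaque). When only coordinates
  are available, a spot is proximal iff its center lies strictly within
  55 µm of the nearest plaque center (strict `<` at the boundary).
* **Enrichment**: Pearson chi-square on the 2×2 in-state × group table,
  1 dof. Yates continuity correction is ON by default to match the
  default of R's `chisq.test` on 2×2 tables; oracle comparisons and the
  worked example use `correction=False`, where the statistic equals
  `Σ(O−E)²/E` exactly. Expected cells below 1 flag the result as
  unreliable but still compute it. Layer groups: external = II–III,
  internal = IV–VI. The same machinery serves tangle (NFT) overlap
  flags; nothing presupposes an NFT effect.
* **Staining**: per sample and category, counts are normalized by the
  layer II–VI total (shares sum to 1 by construction); external and
  internal shares are compared with a two-sided Welch (unequal-variance)
  t-test across samples. Samples with a zero total are excluded with a
  warning; fewer than two samples per group raises an error.

## Synthetic-data model

One top-level seed is split into fixed named RNG streams (cells,
batches, spots, plaques, staining), so adding a generator never perturbs
another's draws and identical configs are byte-identical on re-run.

**Cell tables.** Donor s in group g draws per-cluster values
`t_k = base_k^(1/3) + effect_k·1[g ≠ Control] + ε_k`,
`ε_k ~ N(0, 0.03)`, which are cubed, clipped at 0 (clipping logged) and
renormalized; nuclei counts are multinomial (400 per donor by default,
60 donors split Control/sAD). Effects are injected on the cube-root
scale so the regression recovers them near-linearly; a configuration
whose effect would push a proportion past 1 before renormalization is
rejected. The default baseline composition (50% homeostatic, 2%
activated, 8% interferon, 10% MHC-II, 12% proliferating, 18% other)
reflects the rarity of activated microglia in control cortex and was
fixed once after verifying by closed-form/Monte-Carlo oracle that a 0.2
cube-root effect is recovered with mean β̂ ≈ 0.19. Batch labels are
drawn per cluster from a Dirichlet-multinomial around uniform batch
frequencies with concentration `mixing_concentration` (1e6 default ≈
perfectly mixed; → 0 gives one batch per cluster). Batch is drawn
independently of donor — incoherent as a cohort design but exactly the
marginal structure the mixing metrics consume. Cohort ids mirror batch
ids (four cohorts = four batches). Original labels equal the cluster
name with probability `label_fidelity` (0.9) and a uniformly random
other state otherwise.

**Spot tables.** A 50×40 lattice at 100 µm pitch (hex offset optional —
only center distances matter downstream), rows partitioned into five
equal layer bands II–VI. Plaque centers (12 by default) are uniform on
the slide; a spot overlaps iff its center is within 150 µm (~7 spots per
plaque, ≈ 80 proximal spots per slide). Top-quartile membership of the
activated score is Bernoulli with rates solved so the overall rate is
25% and the overlap/non-overlap odds ratio equals
`activated_odds_ratio`; the score is then placed uniformly within the
corresponding quartile band, so the configured odds ratio holds exactly
at the empirical 75th percentile (additive noise after band placement
would dilute it). `noise_sd` therefore applies to the homeostatic
score, which is a logit-shifted (internal layers IV–VI) noisy uniform.
Tangle flags use independently placed centers with no score coupling.

**Staining tables.** Poisson counts per sample, layer group and
category, with the internal-layer rate multiplied by
`staining_internal_enrichment` (rate ratio r ⇒ expected internal share
r/(1+r)).

**What the generator does not emulate:** gene-expression counts, reads
or images; spatial autocorrelation of scores beyond the plaque effect;
donor-level random effects in batch composition; unbalanced group sizes
or missingness patterns of real cohorts. Passing tests therefore
demonstrate correctness of the metrics and calibration of the tests
under the stated model, not robustness to every property of real data.

## Problem sizes and numerics

The replicated checks use 60-donor × 400-nuclei cohorts (200 replicates
for effect recovery, 500 for type-I error) and 2,000-spot slides (100
seeds for power and size) — sizes at which the Monte-Carlo error of the
reported rates is a few percent and a full run completes in well under a
minute. Quantile ties are resolved by inclusion; entropy uses log base
2 throughout; float comparisons in oracles are at 1e−9–1e−12; CSV output
uses fixed `%.10g` formatting so re-runs are byte-identical.

## Known limitations

* The per-cohort NPMI summary (weighted mean) is a package choice; other
  reductions (max per row, arithmetic mean) are easily computed from the
  emitted matrix.
* The proportion model is a fixed-effects OLS per cluster; no
  compositional transforms (CLR/ILR) or mixed effects are provided.
* The chi-square enrichment treats spots as independent; spatial
  autocorrelation on real slides will make p-values anti-conservative.
* Proximity classification uses spot centers, not capture-area overlap
  geometry.
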
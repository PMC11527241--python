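# gliastate

Analysis toolkit for microglial transcriptional states across integrated
single-cell cohorts and Visium-style spatial transcriptomics slides, aimed
at neurodegeneration researchers who have integrated multi-cohort
microglia data and want to (1) audit the integration, (2) test which
states shift between disease groups, and (3) quantify where states sit in
the cortex relative to amyloid pathology.

## What it computes

**Integration QC.** For each integrated cluster *i* with batch (or
sample) composition `p_ij`, the Shannon mixing entropy
`H(i) = -Σ_j p_ij log2 p_ij` and the cell-count-weighted overall entropy
`Σ_i H(i)·N_i/N`, both normalized by `log2 K` over the K categories
present (the uniform-distribution inner sum `-log2 K` is reported too:
-2 bits for 4 batches, -8.9 for 490 samples). Agreement between each
cohort's original state labels x and the integrated clusters y is scored
with normalized pointwise mutual information,
`npmi(x;y) = log2[p(x,y)/(p(x)p(y))] / (-log2 p(x,y))`, ranging -1
(never co-occur) through 0 (independence) to +1 (perfect alignment).

**Differential proportion analysis.** Each donor's nuclei are tallied per
cluster and divided by the donor's total, then per cluster the model
`proportion^(1/3) ~ sex + disease status` is fitted (Gaussian identity
link, Control as reference); `beta` is the disease shift on the cube-root
proportion scale. Samples with fewer than 10 cells are excluded.

**Spatial state quantification.** Per slide, spots in the top 25% of a
state's prediction scores are flagged in-state; layer-I spots are
excluded. In-state fractions are tabulated per cortical layer (II-VI),
spots are classified amyloid-proximal (direct plaque overlap, or center
distance < 55 µm when only coordinates are available) versus distal, and
enrichment is tested with a Pearson chi-square on the 2×2 table (Yates
correction on by default, matching R's `chisq.test`). Immunostaining
counts are compared between external (II-III) and internal (IV-VI) layers
with a two-sided Welch t-test on shares normalized to the II-VI total.

**Synthetic data.** A seeded generator produces cell tables, spot tables
and staining counts with exactly the structure above — configurable
cube-root group effects, Dirichlet-multinomial batch mixing, layer bands,
plaque placement and a configurable odds ratio of top-quartile activated
scores at plaque-overlapping spots — so every analysis ships with
power/size checks.

## Worked example

```python
import gliastate as g

cfg = g.SyntheticConfig(seed=5, activated_odds_ratio=3.0)
spots = g.exclude_layer_I(g.generate_spot_table(cfg))
spots = g.classify_proximity(spots, pathology="ab")
flagged = g.select_top_quantile(spots, state="activated", q=0.25)
res = g.enrichment_chisq(flagged, "activated", grouping="proximal_vs_distal")
print(res.fractions, res.chi2_stat, res.p_value)
```

prints (see `examples/plaque_proximity.py`):

```
activated in-state fraction: proximal 0.506 vs distal 0.239
chi-square = 28.86 (dof 1), p = 7.76e-08
```

i.e. on a slide simulated with a 3× odds of high activated scores at
plaque-overlapping spots, 50.6% of proximal spots are top-quartile
activated versus 23.9% of distal spots, and the chi-square test rejects
equal fractions. The other capabilities each have a short narrative
script under `examples/` — cohort simulation, mixing entropy, NPMI,
proportion modeling, and staining layer comparison.

A thin CLI mirrors the library:
`gliastate simulate|entropy|npmi|proportions|spatial-layers|spatial-proximity|staining`
(CSV in, tidy CSV + JSON + run manifest out).

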
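"""Compare immunostaining counts between external and internal layers.

Per-sample counts are normalized by the layer II-VI total for each
category, then external (II-III) and internal (IV-VI) shares are compared
with a two-sided Welch t-test.
"""

import gliastate as g

cfg = g.SyntheticConfig(seed=8, staining_internal_enrichment=2.0)
table = g.generate_staining_counts(cfg)

for category in ("P2RY12+", "Abeta+"):
    res = g.staining_layer_comparison(table, category)
    print(f"{category}: mean share II-III {res.mean_external:.3f} vs "
          f"IV-VI {res.mean_internal:.3f}; t = {res.t_stat:.2f}, "
          f"p = {res.p_value:.3g} ({res.n_samples} samples)")

print("\nWith a 2x internal-layer rate, the IV-VI share sits near 2/3 and "
      "the t-test rejects equality of layer-group shares.")
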
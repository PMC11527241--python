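"""Differential proportion analysis of states between disease groups.

Per donor, each cluster's share of nuclei is cube-root transformed and
regressed on sex and disease status; the group coefficient beta is the
shift on the cube-root proportion scale.
"""

import gliastate as g

cfg = g.SyntheticConfig(seed=3, effect_cuberoot=(0, 0.2, 0, 0, 0, 0))
cells = g.filter_min_cells(g.generate_cell_table(cfg))
props = g.compute_proportions(cells)

fits = g.fit_proportion_model(props, contrast=("sAD", "Control"), covariates=["sex"])
print(fits.round(4).to_string(index=False))

avg = g.group_average_composition(props)
print("\nmean composition by group (stacked-barplot table):")
print(avg.pivot(index="cluster_id", columns="disease_group",
                values="mean_proportion").round(3).to_string())
print("\nThe 'activated' beta recovers the simulated 0.2 cube-root "
      "enrichment in sAD donors; other clusters sit near zero.")
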
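"""Generate a synthetic multi-cohort cell table and a Visium-style slide.

The generator emulates the inputs of the downstream analyses: per-donor
transcriptional-state compositions with a disease effect on the cube-root
scale, batch labels per integrated cluster, and a spot lattice with
cortical layer bands and amyloid plaques.
"""

import gliastate as g

cfg = g.SyntheticConfig(
    seed=1,
    effect_cuberoot=(0, 0.2, 0, 0, 0, 0),  # enrich 'activated' in cases
    activated_odds_ratio=3.0,
)
cells = g.generate_cell_table(cfg)
spots = g.generate_spot_table(cfg)

print(f"cells: {len(cells)} rows "
      f"({cells.sample_id.nunique()} donors x {cfg.n_cells_per_sample} nuclei)")
print(cells.head(3).to_string(index=False))
print(f"\nspots: {len(spots)} on a {cfg.grid_rows}x{cfg.grid_cols} lattice, "
      f"{int(spots.ab_overlap.sum())} overlap an amyloid plaque")
print(spots.head(3).to_string(index=False))
print("\nEach cell row is one nucleus with its cohort, donor, batch, "
      "integrated cluster and original state label; each spot row is one "
      "capture area with layer, coordinates and state prediction scores.")
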
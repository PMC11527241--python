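"""Seeded generators for cell tables, spatial spot tables and staining counts.

The generators emulate the statistical structure the downstream analyses
assume:

* donor-level state compositions with disease-group effects injected on the
  cube-root proportion scale (so the compositional regression recovers them
  in expectation),
* batch composition per cluster drawn from a Dirichlet-multinomial whose
  concentration dials mixing from perfectly mixed to fully separated,
* a rectangular (optionally hex-offset) spot lattice with cortical layer
  bands, randomly placed amyloid plaques, and an activated-state score whose
  odds of exceeding its 75th percentile at plaque-overlapping spots follow a
  configured odds ratio.

No gene-expression matrices, reads, or images are simulated.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import (
    INTERNAL_LAYERS,
    LAYERS,
    SyntheticConfig,
)

logger = logging.getLogger(__name__)

CELL_COLUMNS = [
    "cell_id",
    "dataset_id",
    "sample_id",
    "batch_id",
    "cluster_id",
    "original_label",
    "disease_group",
    "sex",
]

SPOT_COLUMNS = [
    "spot_id",
    "sample_id",
    "x_um",
    "y_um",
    "layer",
    "score_homeostatic",
    "score_activated",
    "ab_overlap",
    "nft_overlap",
]


def _sample_proportions(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-sample expected cluster proportions.

    t_k = base_k^(1/3) + effect_k * 1[group != Control] + eps, cubed,
    clipped at 0 and renormalized.  Clipping events are logged.
    """
    base_t = np.asarray(cfg.base_proportions, float) ** (1.0 / 3.0)
    effect = np.asarray(cfg.effect_cuberoot, float)
    samples = sorted(cfg.group_assignment)
    rows = []
    n_clipped = 0
    for s in samples:
        is_case = cfg.group_assignment[s] != "Control"
        t = base_t + (effect if is_case else 0.0)
        t = t + rng.normal(0.0, cfg.proportion_noise_sd, cfg.n_clusters)
        if (t < 0).any():
            n_clipped += 1
        p = np.clip(t, 0.0, None) ** 3
        total = p.sum()
        if total == 0:
            # pathological noise draw; fall back to the baseline mixture
            p = np.asarray(cfg.base_proportions, float).copy()
            total = 1.0
        rows.append(p / total)
    if n_clipped:
        logger.info(
            "clipped negative cube-root draws at 0 for %d of %d samples",
            n_clipped,
            len(samples),
        )
    return pd.DataFrame(rows, index=samples, columns=list(cfg.cluster_names))


def generate_cell_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one record per cell with cohort/sample/batch/cluster labels.

    Returns a cell table with exactly ``n_samples * n_cells_per_sample``
    rows.  Batch labels are drawn per integrated cluster from a
    Dirichlet-multinomial with concentration ``mixing_concentration``; the
    original (cohort-level) state label equals the cluster's name with
    probability ``label_fidelity`` and is a uniformly random other state
    otherwise.
    """
    rng = config.rng("cells")
    brng = config.rng("batches")
    props = _sample_proportions(config, rng)
    n_c = config.n_cells_per_sample
    names = np.asarray(config.cluster_names, dtype=object)

    sample_col, cluster_col, group_col, sex_col = [], [], [], []
    for s in props.index:
        counts = rng.multinomial(n_c, props.loc[s].to_numpy())
        sample_col.append(np.repeat(s, n_c))
        cluster_col.append(np.repeat(names, counts))
        group_col.append(np.repeat(config.group_assignment[s], n_c))
        sex_col.append(np.repeat(config.sex_assignment[s], n_c))
    cluster = np.concatenate(cluster_col)
    n_total = cluster.size

    # batch composition within each cluster: Dirichlet-multinomial around
    # the uniform global batch frequencies
    alpha = np.full(config.n_batches, config.mixing_concentration / config.n_batches)
    batch = np.empty(n_total, dtype=object)
    batch_names = np.array([f"B{b}" for b in range(config.n_batches)], dtype=object)
    for k in names:
        idx = np.where(cluster == k)[0]
        if idx.size == 0:
            continue
        theta = brng.dirichlet(alpha)
        batch[idx] = brng.choice(batch_names, size=idx.size, p=theta)

    # original labels: faithful with prob label_fidelity, else another state
    keep = rng.random(n_total) < config.label_fidelity
    shift = rng.integers(1, config.n_clusters, size=n_total)
    name_index = {n: i for i, n in enumerate(names)}
    pos = np.array([name_index[c] for c in cluster])
    label = np.where(keep, cluster, names[(pos + shift) % config.n_clusters])

    table = pd.DataFrame(
        {
            "cell_id": [f"C{i:07d}" for i in range(n_total)],
            "dataset_id": pd.Series(batch).str.replace("B", "cohort", regex=False),
            "sample_id": np.concatenate(sample_col),
            "batch_id": batch,
            "cluster_id": cluster,
            "original_label": label,
            "disease_group": np.concatenate(group_col),
            "sex": np.concatenate(sex_col),
        }
    )
    return table


def _spot_lattice(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = np.repeat(np.arange(cfg.grid_rows), cfg.grid_cols)
    cols = np.tile(np.arange(cfg.grid_cols), cfg.grid_rows)
    x = cols * cfg.spot_pitch_um
    if cfg.hex_offset:
        x = x + (rows % 2) * cfg.spot_pitch_um / 2.0
    y = rows * cfg.spot_pitch_um
    # layer bands partition rows: II..VI in order
    bounds = np.cumsum((0,) + tuple(cfg.layer_bands))
    layer = np.empty(cfg.grid_rows, dtype=object)
    for i, lay in enumerate(LAYERS[1:]):  # II..VI
        layer[bounds[i] : bounds[i + 1]] = lay
    return pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "x_um": x.astype(float),
            "y_um": y.astype(float),
            "layer": layer[rows],
        }
    )


def _overlap_flags(
    xy: np.ndarray, centers: np.ndarray, radius: float
) -> np.ndarray:
    if centers.size == 0:
        return np.zeros(len(xy), dtype=bool)
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return (d2.min(axis=1) ** 0.5) < radius


def _solve_overlap_rate(n1: int, n0: int, odds_ratio: float, q: float = 0.25) -> tuple:
    """Bernoulli rates (p1 at overlapping spots, p0 elsewhere) such that the
    overall top-quantile mass is q and the odds ratio p1/(1-p1) : p0/(1-p0)
    equals ``odds_ratio``."""
    if n1 == 0:
        return 0.0, q
    total = q * (n1 + n0)

    def gap(p0: float) -> float:
        p1 = odds_ratio * p0 / (1 + (odds_ratio - 1) * p0)
        return n1 * p1 + n0 * p0 - total

    p0 = brentq(gap, 1e-12, 1 - 1e-12)
    p1 = odds_ratio * p0 / (1 + (odds_ratio - 1) * p0)
    return p1, p0


def generate_spot_table(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a Visium-style spot table for one slide.

    Spots sit on a ``grid_rows x grid_cols`` lattice with pitch
    ``spot_pitch_um``; each spot carries a cortical layer (II..VI from
    ``layer_bands``), an amyloid-overlap flag (center within
    ``plaque_radius_um`` of a plaque center), an independent tangle-overlap
    flag, and homeostatic/activated prediction scores in [0, 1].

    The activated score is constructed so that the odds of a spot lying in
    the top quartile of the slide's activated scores are
    ``activated_odds_ratio`` times higher at plaque-overlapping spots.
    """
    if config.n_plaques == 0 and config.activated_odds_ratio != 1.0:
        warnings.warn(
            "activated_odds_ratio != 1 with n_plaques = 0: the enrichment "
            "effect cannot be exercised",
            UserWarning,
            stacklevel=2,
        )
    rng = config.rng("spots")
    prng = config.rng("plaques")
    spots = _spot_lattice(config)
    n = len(spots)
    xy = spots[["x_um", "y_um"]].to_numpy()
    xmax = spots["x_um"].max()
    ymax = spots["y_um"].max()

    def centers(k: int) -> np.ndarray:
        if k == 0:
            return np.empty((0, 2))
        return np.column_stack(
            [prng.uniform(0, xmax, k), prng.uniform(0, ymax, k)]
        )

    ab = _overlap_flags(xy, centers(config.n_plaques), config.plaque_radius_um)
    nft = _overlap_flags(xy, centers(config.n_tangles), config.plaque_radius_um)

    # activated score: draw top-quartile membership at the configured odds,
    # then place the score uniformly within the corresponding quartile band
    p1, p0 = _solve_overlap_rate(int(ab.sum()), int(n - ab.sum()), config.activated_odds_ratio)
    high = rng.random(n) < np.where(ab, p1, p0)
    act = np.where(
        high, rng.uniform(0.75, 1.0, n), rng.uniform(0.0, 0.75, n)
    )

    # homeostatic score: logit-shifted upward in internal layers, noisy
    base = rng.uniform(0.02, 0.98, n)
    internal = spots["layer"].isin(INTERNAL_LAYERS).to_numpy()
    shifted = expit(logit(base) + config.homeostatic_internal_shift * internal)
    homeo = np.clip(shifted + rng.normal(0.0, config.noise_sd, n), 0.0, 1.0)

    out = pd.DataFrame(
        {
            "spot_id": [f"SP{i:05d}" for i in range(n)],
            "sample_id": "slide0",
            "x_um": spots["x_um"],
            "y_um": spots["y_um"],
            "layer": spots["layer"],
            "score_homeostatic": homeo,
            "score_activated": act,
            "ab_overlap": ab,
            "nft_overlap": nft,
        }
    )
    return out


def generate_staining_counts(config: SyntheticConfig) -> pd.DataFrame:
    """Per-sample, per-layer-group immunostaining counts.

    Counts for the categories P2RY12+, Abeta+, P2RY12+/Abeta+ and
    P2RY12+/Abeta- are Poisson with base rate ``staining_base_rate``; the
    internal layer group IV-VI gets its rate multiplied by
    ``staining_internal_enrichment``.
    """
    rng = config.rng("staining")
    categories = ["P2RY12+", "Abeta+", "P2RY12+/Abeta+", "P2RY12+/Abeta-"]
    rows = []
    for s in sorted(config.group_assignment):
        for cat in categories:
            lam_ext = config.staining_base_rate
            lam_int = config.staining_base_rate * config.staining_internal_enrichment
            rows.append((s, "II-III", cat, int(rng.poisson(lam_ext))))
            rows.append((s, "IV-VI", cat, int(rng.poisson(lam_int))))
    table = pd.DataFrame(rows, columns=["sample_id", "layer_group", "category", "count"])
    if config.staining_base_rate == 0:
        warnings.warn("staining_base_rate = 0: all counts are zero", UserWarning, stacklevel=2)
    return table
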
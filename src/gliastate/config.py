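"""Configuration for the synthetic cohort / slide generator.

A single :class:`SyntheticConfig` drives all three generators (cell table,
spot table, staining counts).  One top-level ``seed`` is split into named,
independent RNG streams, so adding a generator never perturbs the draws of
another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import yaml

#: canonical microglial transcriptional states used by the default config
DEFAULT_STATES = (
    "homeostatic",
    "activated",
    "interferon",
    "mhc2",
    "proliferating",
    "other",
)

#: baseline state composition of a control donor (fractions of nuclei).
#: Activated microglia are rare in control cortex, hence the small baseline.
DEFAULT_BASE_PROPORTIONS = (0.50, 0.02, 0.08, 0.10, 0.12, 0.18)

DISEASE_GROUPS = (
    "Control",
    "sAD",
    "ADAD",
    "earlyAD",
    "lateAD",
    "Presymptomatic",
    "Other",
)

# fixed spawn keys: stream identity is positional, never perturbed by
# adding new streams at the end
_STREAMS = {"cells": 0, "batches": 1, "spots": 2, "plaques": 3, "staining": 4}


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


def _default_groups(n_samples: int) -> Dict[str, str]:
    # half Control, half sporadic AD, interleaved so group is balanced
    return {
        f"S{i:03d}": ("Control" if i % 2 == 0 else "sAD")
        for i in range(n_samples)
    }


def _default_sexes(n_samples: int) -> Dict[str, str]:
    return {f"S{i:03d}": ("M" if (i // 2) % 2 == 0 else "F") for i in range(n_samples)}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort and Visium-style slide.

    Defaults describe a desk-scale study: 60 donors split Control / sAD,
    4 cohorts acting as batches, six transcriptional states, and a
    2,000-spot slide with five cortical layer bands (II-VI).
    """

    seed: int = 0
    n_samples: int = 60
    n_cells_per_sample: int = 400
    n_batches: int = 4
    n_clusters: int = len(DEFAULT_STATES)
    cluster_names: Sequence[str] = DEFAULT_STATES
    base_proportions: Sequence[float] = DEFAULT_BASE_PROPORTIONS
    group_assignment: Dict[str, str] = field(default_factory=dict)
    sex_assignment: Dict[str, str] = field(default_factory=dict)
    #: additive effect on the cube-root proportion scale, applied to
    #: non-control samples, one entry per cluster
    effect_cuberoot: Sequence[float] = (0.0,) * len(DEFAULT_STATES)
    #: Dirichlet concentration for batch composition within clusters;
    #: large -> perfectly mixed, -> 0 -> one batch per cluster
    mixing_concentration: float = 1e6
    #: sd of the donor-level Gaussian jitter on the cube-root scale
    proportion_noise_sd: float = 0.03
    #: probability a cell keeps its cluster's name as original label
    label_fidelity: float = 0.9

    # ---- spatial slide ----
    grid_rows: int = 50
    grid_cols: int = 40
    spot_pitch_um: float = 100.0
    hex_offset: bool = False
    #: rows per cortical layer, ordered II..VI; must sum to grid_rows
    layer_bands: Sequence[int] = (10, 10, 10, 10, 10)
    n_plaques: int = 12
    n_tangles: int = 12
    plaque_radius_um: float = 150.0
    activated_odds_ratio: float = 1.0
    homeostatic_internal_shift: float = 0.0
    noise_sd: float = 0.05

    # ---- staining counts ----
    staining_base_rate: float = 100.0
    staining_internal_enrichment: float = 1.0

    def __post_init__(self) -> None:
        self.cluster_names = tuple(self.cluster_names)
        self.base_proportions = tuple(float(v) for v in self.base_proportions)
        self.effect_cuberoot = tuple(float(v) for v in self.effect_cuberoot)
        self.layer_bands = tuple(int(v) for v in self.layer_bands)
        if not self.group_assignment:
            self.group_assignment = _default_groups(self.n_samples)
        if not self.sex_assignment:
            self.sex_assignment = _default_sexes(self.n_samples)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        p = np.asarray(self.base_proportions, dtype=float)
        if p.size != self.n_clusters:
            raise ConfigError(
                f"base_proportions has {p.size} entries for {self.n_clusters} clusters"
            )
        if (p < 0).any():
            raise ConfigError("base_proportions entries must be >= 0")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigError(f"base_proportions sum to {p.sum()!r}, not 1")
        for name, v in (
            ("n_samples", self.n_samples),
            ("n_cells_per_sample", self.n_cells_per_sample),
            ("n_batches", self.n_batches),
            ("n_clusters", self.n_clusters),
            ("grid_rows", self.grid_rows),
            ("grid_cols", self.grid_cols),
        ):
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.activated_odds_ratio <= 0:
            raise ConfigError("activated_odds_ratio must be > 0")
        if len(self.cluster_names) != self.n_clusters:
            raise ConfigError("cluster_names length must equal n_clusters")
        if len(self.effect_cuberoot) != self.n_clusters:
            raise ConfigError("effect_cuberoot length must equal n_clusters")
        if sum(self.layer_bands) != self.grid_rows:
            raise ConfigError(
                f"layer_bands {tuple(self.layer_bands)} must partition the "
                f"{self.grid_rows} grid rows exactly"
            )
        if len(self.layer_bands) != 5:
            raise ConfigError("layer_bands must have 5 entries (layers II..VI)")
        # an effect that pushes a cube-root proportion past 1 before
        # renormalization is rejected outright
        t = p ** (1.0 / 3.0) + np.asarray(self.effect_cuberoot, dtype=float)
        if (t > 1.0).any():
            bad = [self.cluster_names[i] for i in np.where(t > 1.0)[0]]
            raise ConfigError(
                f"effect_cuberoot drives proportion above 1 before "
                f"renormalization for cluster(s) {bad}"
            )
        groups = set(self.group_assignment.values())
        unknown = groups - set(DISEASE_GROUPS)
        if unknown:
            raise ConfigError(f"unknown disease group(s) {sorted(unknown)}")

    # -- rng ----------------------------------------------------------
    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named stream of this config's seed."""
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,))
        )

    # -- (de)serialization --------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cluster_names"] = list(self.cluster_names)
        d["base_proportions"] = list(map(float, self.base_proportions))
        d["effect_cuberoot"] = list(map(float, self.effect_cuberoot))
        d["layer_bands"] = list(map(int, self.layer_bands))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


LAYERS = ("I", "II", "III", "IV", "V", "VI")
EXTERNAL_LAYERS = ("II", "III")
INTERNAL_LAYERS = ("IV", "V", "VI")
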
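import dataclasses

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gliastate as g

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    return g.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def cell_table(default_config):
    return g.generate_cell_table(default_config)


@pytest.fixture(scope="session")
def spot_table():
    cfg = g.SyntheticConfig(seed=11, activated_odds_ratio=3.0)
    return g.generate_spot_table(cfg)


@pytest.fixture
def tiny_cells():
    """Hand-built four-cell-cluster table used by entropy/NPMI unit tests."""
    rows = []
    i = 0
    for cluster, batches in {
        "c0": ["B0"] * 4,          # degenerate: one batch
        "c1": ["B0", "B1", "B2", "B3"],  # perfectly balanced over 4 batches
        "c2": ["B0", "B0", "B0", "B1"],  # counts (3, 1)
    }.items():
        for b in batches:
            rows.append(
                {
                    "cell_id": f"c{i:03d}",
                    "dataset_id": "cohortX",
                    "sample_id": f"S{i % 3}",
                    "batch_id": b,
                    "cluster_id": cluster,
                    "original_label": cluster,
                    "disease_group": "Control",
                    "sex": "F",
                }
            )
            i += 1
    return pd.DataFrame(rows)


def make_config(**kw):
    base = dict(seed=0)
    base.update(kw)
    return g.SyntheticConfig(**base)
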
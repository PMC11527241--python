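"""Integration quality metrics: mixing entropy and label-cluster NPMI.

After multi-cohort integration, a well-mixed clustering spreads every batch
(and every sample) evenly across each integrated cluster.  Two metrics
quantify this:

* **Mixing entropy** — for cluster *i* with category composition
  ``p_ij`` over batches or samples, ``H(i) = -sum_j p_ij log2 p_ij``; the
  overall value is the cell-count-weighted mean over clusters.  Both are
  normalized by ``log2(K)``, the maximum entropy over the K categories
  present, so 1 means perfectly mixed and 0 means a single-category
  cluster.  The (negative) inner sum ``sum_j p_ij log2 p_ij`` and the
  uniform-distribution constant ``-log2 K`` are surfaced as well, since
  normalization constants are conventionally quoted on that scale
  (4 categories -> -2 bits).

* **NPMI** — normalized pointwise mutual information between each cohort's
  original transcriptional-state labels x and the integrated clusters y:
  ``npmi(x;y) = pmi(x;y) / h(x,y)`` with ``pmi = log2 p(x,y)/(p(x)p(y))``
  and ``h = -log2 p(x,y)``.  Values range from -1 (never co-occur, assigned
  by convention when p(x,y) = 0) through 0 (independence) to +1 (perfect
  alignment).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPING_COLUMNS = {"batch": "batch_id", "sample": "sample_id"}


class EmptyInputError(ValueError):
    """No cells left to analyze."""


def filter_min_cells(cells: pd.DataFrame, min_cells: int = 10) -> pd.DataFrame:
    """Drop samples contributing fewer than ``min_cells`` cells.

    The boundary is inclusive: a sample with exactly ``min_cells`` cells is
    retained.  Removals are logged with per-sample counts.
    """
    if min_cells < 0:
        raise ValueError(f"min_cells must be >= 0, got {min_cells}")
    counts = cells["sample_id"].value_counts()
    keep = counts.index[counts >= min_cells]
    dropped = counts[counts < min_cells]
    if len(dropped):
        logger.info(
            "filter_min_cells: removed %d sample(s) below %d cells: %s",
            len(dropped),
            min_cells,
            dropped.to_dict(),
        )
    return cells[cells["sample_id"].isin(keep)].copy()


def max_inner_sum(n_categories: int) -> float:
    """Value of ``sum_j p_j log2 p_j`` at the uniform distribution.

    This is ``-log2(n_categories)``, the normalization constant for the
    mixing entropy (e.g. 4 categories -> -2 bits).
    """
    if n_categories < 1:
        raise ValueError(f"n_categories must be >= 1, got {n_categories}")
    return -float(np.log2(n_categories))


@dataclass
class MixingReport:
    """Per-cluster and overall normalized mixing entropies."""

    grouping: str
    per_cluster: pd.DataFrame  # cluster_id, n_cells, inner_sum, raw_entropy, normalized_entropy
    overall_raw: float
    overall_normalized: float
    n_categories: int
    max_inner_sum: float

    def __post_init__(self) -> None:
        norm = self.per_cluster["normalized_entropy"]
        assert ((norm >= -1e-12) & (norm <= 1 + 1e-12)).all()


def cluster_entropy(cells: pd.DataFrame, grouping: str = "batch") -> MixingReport:
    """Shannon mixing entropy of batch/sample composition per cluster.

    For each integrated cluster the entropy of its category composition is
    computed in bits (0 log 0 = 0) and normalized by log2(K) over the K
    categories present globally; the overall value is the
    cell-count-weighted mean of the per-cluster entropies.
    """
    if grouping not in GROUPING_COLUMNS:
        raise ValueError(f"grouping must be one of {sorted(GROUPING_COLUMNS)}")
    col = GROUPING_COLUMNS[grouping]
    data = cells.dropna(subset=["cluster_id", col])
    n_dropped = len(cells) - len(data)
    if n_dropped:
        logger.info("cluster_entropy: dropped %d cell(s) with missing fields", n_dropped)
    if data.empty:
        raise EmptyInputError("no cells with cluster and grouping labels")

    counts = pd.crosstab(data["cluster_id"], data[col])
    k = counts.shape[1]
    n_i = counts.sum(axis=1)
    p = counts.div(n_i, axis=0).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    inner = terms.sum(axis=1)  # sum p log2 p, <= 0
    raw = -inner + 0.0  # avoid negative zero in reports
    if k == 1:
        warnings.warn(
            "only one category present: maximum entropy is 0, normalized "
            "entropy defined as 0",
            UserWarning,
            stacklevel=2,
        )
        norm = np.zeros_like(raw)
        overall_norm = 0.0
    else:
        norm = raw / np.log2(k)
        norm = np.clip(norm, 0.0, 1.0)
    per_cluster = pd.DataFrame(
        {
            "cluster_id": counts.index,
            "n_cells": n_i.to_numpy(),
            "inner_sum": inner,
            "raw_entropy": raw,
            "normalized_entropy": norm,
        }
    ).reset_index(drop=True)
    weights = n_i.to_numpy() / n_i.to_numpy().sum()
    overall_raw = float((raw * weights).sum())
    if k > 1:
        overall_norm = float(overall_raw / np.log2(k))
    return MixingReport(
        grouping=grouping,
        per_cluster=per_cluster,
        overall_raw=overall_raw,
        overall_normalized=float(overall_norm),
        n_categories=k,
        max_inner_sum=max_inner_sum(k),
    )


@dataclass
class NpmiMatrix:
    """Normalized PMI between original labels (rows) and clusters (columns)."""

    npmi: pd.DataFrame
    joint: pd.DataFrame
    p_label: pd.Series
    p_cluster: pd.Series
    summary: float  # p(x,y)-weighted mean of npmi

    def __post_init__(self) -> None:
        v = self.npmi.to_numpy()
        assert (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()
        assert abs(self.joint.to_numpy().sum() - 1.0) < 1e-12


def _npmi_from_joint(joint: pd.DataFrame) -> NpmiMatrix:
    p = joint.to_numpy(dtype=float)
    total = p.sum()
    p = p / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    # zero-marginal rows/columns carry no cells; exclude with a log entry
    keep_r = px > 0
    keep_c = py > 0
    if not keep_r.all() or not keep_c.all():
        logger.info(
            "npmi_matrix: excluded %d empty label(s) and %d empty cluster(s)",
            int((~keep_r).sum()),
            int((~keep_c).sum()),
        )
        joint = joint.loc[joint.index[keep_r], joint.columns[keep_c]]
        p = p[np.ix_(keep_r, keep_c)]
        p = p / p.sum()
        px = p.sum(axis=1)
        py = p.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(p / np.outer(px, py))
        h = -np.log2(p)
        npmi = pmi / h
    # conventions: p(x,y)=0 -> -1 (never co-occur); p(x,y)=1 -> +1
    npmi = np.where(p == 0, -1.0, npmi)
    npmi = np.where(p == 1, 1.0, npmi)
    npmi_df = pd.DataFrame(npmi, index=joint.index, columns=joint.columns)
    joint_df = pd.DataFrame(p, index=joint.index, columns=joint.columns)
    summary = float((p * npmi).sum())
    return NpmiMatrix(
        npmi=npmi_df,
        joint=joint_df,
        p_label=pd.Series(px, index=joint.index, name="p_label"),
        p_cluster=pd.Series(py, index=joint.columns, name="p_cluster"),
        summary=summary,
    )


def npmi_matrix(
    cells: pd.DataFrame, by_cohort: bool = False
) -> Union[NpmiMatrix, Dict[str, NpmiMatrix]]:
    """NPMI between original state labels and integrated clusters.

    With ``by_cohort=True`` one matrix is returned per ``dataset_id``,
    mirroring a per-cohort agreement check; otherwise a single pooled
    matrix.
    """
    data = cells.dropna(subset=["original_label", "cluster_id"])
    n_dropped = len(cells) - len(data)
    if n_dropped:
        logger.info("npmi_matrix: dropped %d cell(s) with missing label/cluster", n_dropped)
    if data.empty:
        raise EmptyInputError("no cells with both original label and cluster")
    if by_cohort:
        return {
            cohort: _npmi_from_joint(
                pd.crosstab(sub["original_label"], sub["cluster_id"])
            )
            for cohort, sub in data.groupby("dataset_id", observed=True)
        }
    return _npmi_from_joint(pd.crosstab(data["original_label"], data["cluster_id"]))
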
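"""Differential proportion analysis of transcriptional states.

Each donor's nuclei are tallied per integrated cluster and divided by the
donor's total nuclei count, giving a composition that sums to one.  Per
cluster, the cube-root-transformed proportion is regressed on sex and a
disease-status indicator (Control as reference) with an identity-link
Gaussian linear model; the coefficient on the status indicator is the
effect of disease on the cube-root proportion scale.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class SingularDesignError(ValueError):
    """Design matrix is rank deficient (collinear columns)."""


def compute_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster proportions with sample covariates.

    Returns one row per (sample, cluster) including clusters a sample has
    zero cells in; ``proportion`` is the share of the sample's total
    nuclei, so per-sample proportions sum to 1.
    """
    counts = pd.crosstab(cells["sample_id"], cells["cluster_id"])
    totals = counts.sum(axis=1)
    props = counts.div(totals, axis=0)

    covars = (
        cells[["sample_id", "disease_group", "sex"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    tidy = (
        props.stack()
        .rename("proportion")
        .reset_index()
        .merge(
            counts.stack().rename("n_cells").reset_index(),
            on=["sample_id", "cluster_id"],
        )
        .merge(covars, left_on="sample_id", right_index=True)
    )
    return tidy[
        ["sample_id", "cluster_id", "n_cells", "proportion", "disease_group", "sex"]
    ]


def _design(
    sub: pd.DataFrame, case_group: str, covariates: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    cols = [np.ones(len(sub))]
    names = ["Intercept"]
    for cov in covariates:
        levels = sorted(sub[cov].unique())
        for lev in levels[1:]:  # treatment coding, first level reference
            cols.append((sub[cov] == lev).to_numpy(float))
            names.append(f"{cov}[{lev}]")
    cols.append((sub["disease_group"] == case_group).to_numpy(float))
    names.append(f"group[{case_group}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the columns involved in the collinearity
        bad = []
        for j in range(X.shape[1]):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise SingularDesignError(
            f"singular design: collinear column(s) {bad or names}"
        )
    return X, names


def fit_proportion_model(
    props: pd.DataFrame,
    contrast: Tuple[str, str] = ("sAD", "Control"),
    covariates: Sequence[str] = ("sex",),
    clusters: Optional[Sequence[str]] = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Fit ``proportion^(1/3) ~ covariates + group`` per cluster.

    ``contrast`` is (case_group, reference_group); only samples from those
    two groups enter the fit.  Returns one row per cluster with the group
    coefficient ``beta`` (cube-root scale), its standard error, and the
    two-sided p-value.  ``bh=True`` adds Benjamini-Hochberg q-values
    across clusters.
    """
    case, ref = contrast
    missing = props[["disease_group", "sex"]].isna().any(axis=1)
    if missing.any():
        dropped = props.loc[missing, "sample_id"].nunique()
        logger.info("fit_proportion_model: removed %d sample(s) without covariates", dropped)
        props = props[~missing]
    sub = props[props["disease_group"].isin([case, ref])]
    for grp in (case, ref):
        n = sub.loc[sub["disease_group"] == grp, "sample_id"].nunique()
        if n < 2:
            raise ValueError(f"contrast group {grp!r} has {n} sample(s); need >= 2")

    rows = []
    cluster_ids = clusters if clusters is not None else sorted(sub["cluster_id"].unique())
    for cid in cluster_ids:
        block = sub[sub["cluster_id"] == cid].sort_values("sample_id")
        y = block["proportion"].to_numpy() ** (1.0 / 3.0)
        X, names = _design(block, case, covariates)
        fit = sm.OLS(y, X).fit()
        j = names.index(f"group[{case}]")
        rows.append(
            {
                "cluster_id": cid,
                "contrast": f"{case} vs {ref}",
                "beta": fit.params[j],
                "se": fit.bse[j],
                "p_value": fit.pvalues[j],
                "n_samples": int(len(block)),
                "covariates": "+".join(covariates),
            }
        )
    out = pd.DataFrame(rows)
    if bh:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def group_average_composition(props: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-sample proportions within each disease group.

    The result is the stacked-barplot table: per-group means over clusters
    sum to 1.
    """
    out = (
        props.groupby(["disease_group", "cluster_id"], observed=True)["proportion"]
        .mean()
        .rename("mean_proportion")
        .reset_index()
    )
    return out
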
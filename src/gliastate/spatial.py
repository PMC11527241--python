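"""Spatial quantification of transcriptional states on Visium-style slides.

Spots carrying per-state prediction scores are reduced to an in-state flag
by selecting the top quantile (default 25%) of each state's scores within a
sample.  Downstream, in-state spots are counted per cortical layer
(fractions of the layer's spots), classified as plaque-proximal or distal
(overlap annotation, or a <55 um center distance when only coordinates are
available), and compared between groups with a Pearson chi-square test on
the 2x2 contingency table.  Immunostaining counts are compared between the
external (II-III) and internal (IV-VI) layer groups with a Welch t-test on
shares normalized to the layer II-VI total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import EXTERNAL_LAYERS, INTERNAL_LAYERS

logger = logging.getLogger(__name__)


class MissingAnnotationError(ValueError):
    """Neither overlap flags nor plaque centers are available."""


class InsufficientReplicationError(ValueError):
    """Fewer than two samples per group after exclusions."""


def exclude_layer_I(spots: pd.DataFrame) -> pd.DataFrame:
    """Remove layer-I spots (sparsely captured; excluded from analyses)."""
    n = int((spots["layer"] == "I").sum())
    if n:
        logger.info("exclude_layer_I: removed %d layer-I spot(s)", n)
    return spots[spots["layer"] != "I"].copy()


def _top_quantile_threshold(scores: np.ndarray, q: float) -> float:
    """Nearest-rank-higher (1-q)-quantile: the value at 1-based rank
    floor((1-q)*n) + 1 of the sorted scores.  Spots scoring >= it are
    in-state; ties at the threshold are all included."""
    n = scores.size
    rank = int(np.floor((1.0 - q) * n)) + 1  # 1-based
    rank = min(rank, n)
    return float(np.sort(scores)[rank - 1])


def select_top_quantile(
    spots: pd.DataFrame, state: str, q: float = 0.25
) -> pd.DataFrame:
    """Flag spots in the top ``q`` fraction of a state's scores per sample.

    Adds a boolean ``in_state`` column (and records the state name in
    ``in_state_of``).  The threshold is the nearest-rank-higher
    (1-q)-quantile of the state's scores within each sample; ties at the
    threshold are all included, so between ceil(q*n) and n spots are
    selected.
    """
    if not (0 < q <= 1):
        raise ValueError(f"q must be in (0, 1], got {q}")
    col = f"score_{state}"
    if col not in spots.columns:
        raise KeyError(f"missing score column {col!r}")
    out = spots.copy()
    out["in_state"] = False
    for _, idx in out.groupby("sample_id", observed=True).groups.items():
        s = out.loc[idx, col].to_numpy(float)
        thr = _top_quantile_threshold(s, q)
        if np.all(s == s[0]):
            warnings.warn(
                "all scores equal within a sample: every spot selected",
                UserWarning,
                stacklevel=2,
            )
        out.loc[idx, "in_state"] = s >= thr
    out["in_state_of"] = state
    return out


def layer_state_fractions(spots: pd.DataFrame, state: str) -> pd.DataFrame:
    """Fraction of each cortical layer's spots that are in-state.

    Expects ``select_top_quantile`` to have been applied.  Layers II-VI are
    always emitted; a layer with zero spots yields a missing fraction with
    a warning.
    """
    if "in_state" not in spots.columns:
        raise ValueError("run select_top_quantile first (no in_state column)")
    layers = ["II", "III", "IV", "V", "VI"]
    rows = []
    for lay in layers:
        block = spots[spots["layer"] == lay]
        total = len(block)
        if total == 0:
            warnings.warn(f"layer {lay} has no spots; fraction undefined", UserWarning, stacklevel=2)
            rows.append((lay, 0, 0, np.nan))
        else:
            k = int(block["in_state"].sum())
            rows.append((lay, k, total, k / total))
    return pd.DataFrame(rows, columns=["layer", "n_in_state", "n_spots", "fraction"]).assign(state=state)


def classify_proximity(
    spots: pd.DataFrame,
    pathology: str = "ab",
    plaque_centers: Optional[np.ndarray] = None,
    radius_um: float = 55.0,
) -> pd.DataFrame:
    """Label every spot proximal or distal to amyloid plaques (or tangles).

    Default mode uses the per-spot overlap annotation (direct overlap =
    proximal).  When ``plaque_centers`` (an (n, 2) array of x/y in um) is
    given, a spot is proximal iff its center lies strictly within
    ``radius_um`` of the nearest plaque center.
    """
    if pathology not in ("ab", "nft"):
        raise ValueError("pathology must be 'ab' or 'nft'")
    out = spots.copy()
    if plaque_centers is not None:
        centers = np.asarray(plaque_centers, float).reshape(-1, 2)
        if centers.size == 0:
            prox = np.zeros(len(out), dtype=bool)
        else:
            xy = out[["x_um", "y_um"]].to_numpy(float)
            d = np.sqrt(((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2))
            prox = d.min(axis=1) < radius_um
    else:
        flag = f"{pathology}_overlap"
        if flag not in out.columns:
            raise MissingAnnotationError(
                f"no {flag} column and no plaque centers provided"
            )
        prox = out[flag].astype(bool).to_numpy()
    out["proximity"] = np.where(prox, "proximal", "distal")
    return out


@dataclass
class EnrichmentResult:
    """Chi-square enrichment of an in-state flag between two spot groups."""

    state: str
    grouping: str
    group_names: Tuple[str, str]
    contingency: np.ndarray  # rows: group A / B; cols: in-state / not
    fractions: Tuple[float, float]
    chi2_stat: float
    dof: int
    p_value: float
    correction: bool
    low_expected_count: bool = False


def _layer_group(layer: pd.Series) -> pd.Series:
    grp = pd.Series(np.nan, index=layer.index, dtype=object)
    grp[layer.isin(EXTERNAL_LAYERS)] = "external"
    grp[layer.isin(INTERNAL_LAYERS)] = "internal"
    return grp


def enrichment_chisq(
    spots: pd.DataFrame,
    state: str,
    grouping: str = "proximal_vs_distal",
    correction: bool = True,
) -> EnrichmentResult:
    """Pearson chi-square test of in-state fraction between two spot groups.

    ``grouping`` is ``proximal_vs_distal`` (requires ``classify_proximity``)
    or ``external_vs_internal`` (cortical layers II-III vs IV-VI).  Yates
    continuity correction is on by default, matching the common default of
    R's ``chisq.test`` on 2x2 tables.  If any expected cell count falls
    below 1 the result is flagged but still computed.
    """
    if "in_state" not in spots.columns:
        raise ValueError("run select_top_quantile first (no in_state column)")
    if grouping == "proximal_vs_distal":
        if "proximity" not in spots.columns:
            raise ValueError("run classify_proximity first (no proximity column)")
        g = spots["proximity"]
        names = ("proximal", "distal")
    elif grouping == "external_vs_internal":
        g = _layer_group(spots["layer"])
        names = ("external", "internal")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    table = np.zeros((2, 2), dtype=int)
    fractions = []
    for r, name in enumerate(names):
        mask = (g == name).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"group {name!r} has no spots")
        k = int(spots.loc[mask, "in_state"].sum())
        table[r] = (k, int(mask.sum()) - k)
        fractions.append(k / mask.sum())

    chi2, p, dof, expected = stats.chi2_contingency(table, correction=correction)
    low = bool((expected < 1).any())
    if low:
        warnings.warn("expected cell count < 1: chi-square approximation unreliable", UserWarning, stacklevel=2)
    return EnrichmentResult(
        state=state,
        grouping=grouping,
        group_names=names,
        contingency=table,
        fractions=(float(fractions[0]), float(fractions[1])),
        chi2_stat=float(chi2),
        dof=int(dof),
        p_value=float(p),
        correction=correction,
        low_expected_count=low,
    )


@dataclass
class StainingComparison:
    category: str
    t_stat: float
    p_value: float
    mean_external: float
    mean_internal: float
    n_samples: int


def normalize_staining(staining: pd.DataFrame) -> pd.DataFrame:
    """Per-sample shares of each category's count over the layer II-VI total.

    Samples whose II-VI total is zero for a category are excluded with a
    warning; shares within (sample, category) sum to 1.
    """
    out = staining.copy()
    totals = out.groupby(["sample_id", "category"], observed=True)["count"].transform("sum")
    zero = totals == 0
    if zero.any():
        bad = out.loc[zero, "sample_id"].unique().tolist()
        warnings.warn(f"zero II-VI total for sample(s) {bad}: excluded", UserWarning, stacklevel=2)
        out = out[~zero]
        totals = totals[~zero]
    out["share"] = out["count"] / totals
    return out


def staining_layer_comparison(staining: pd.DataFrame, category: str) -> StainingComparison:
    """Welch two-sided t-test of II-III vs IV-VI shares across samples."""
    norm = normalize_staining(staining[staining["category"] == category])
    ext = norm.loc[norm["layer_group"] == "II-III", "share"].to_numpy()
    itn = norm.loc[norm["layer_group"] == "IV-VI", "share"].to_numpy()
    if len(ext) < 2 or len(itn) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples per layer group, got {len(ext)} external / {len(itn)} internal"
        )
    t, p = stats.ttest_ind(ext, itn, equal_var=False)
    return StainingComparison(
        category=category,
        t_stat=float(t),
        p_value=float(p),
        mean_external=float(ext.mean()),
        mean_internal=float(itn.mean()),
        n_samples=int(norm["sample_id"].nunique()),
    )
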
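"""Spatial state quantification vs brute-force counting and hand formulas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gliastate as g
from gliastate.spatial import (
    InsufficientReplicationError,
    MissingAnnotationError,
    _top_quantile_threshold,
)


def _spots(scores, layers=None, sample="s0", ab=None):
    n = len(scores)
    return pd.DataFrame(
        {
            "spot_id": [f"sp{i}" for i in range(n)],
            "sample_id": sample,
            "x_um": np.arange(n, dtype=float),
            "y_um": 0.0,
            "layer": layers if layers is not None else ["II"] * n,
            "score_activated": scores,
            "ab_overlap": ab if ab is not None else [False] * n,
        }
    )


class TestExcludeLayerI:
    def test_removal_and_identity(self):
        spots = _spots([0.1] * 10, layers=["I"] * 3 + ["II"] * 7)
        assert len(g.exclude_layer_I(spots)) == 7
        no_i = _spots([0.1] * 4, layers=["III"] * 4)
        pd.testing.assert_frame_equal(g.exclude_layer_I(no_i), no_i)

    def test_all_layer_I_gives_empty(self):
        spots = _spots([0.1] * 3, layers=["I"] * 3)
        assert g.exclude_layer_I(spots).empty


class TestSelectTopQuantile:
    def test_strict_ordering_selects_top_quarter(self):
        out = g.select_top_quantile(_spots([0.1, 0.2, 0.3, 0.9]), "activated", 0.25)
        assert out.loc[out["in_state"], "score_activated"].tolist() == [0.9]

    def test_ties_at_threshold_all_included(self):
        out = g.select_top_quantile(
            _spots([0.1] * 5 + [0.8] * 3), "activated", 0.25
        )
        assert out["in_state"].sum() == 3
        assert (out.loc[out["in_state"], "score_activated"] == 0.8).all()

    def test_q_one_selects_all(self):
        out = g.select_top_quantile(_spots([0.4, 0.5, 0.6]), "activated", 1.0)
        assert out["in_state"].all()

    def test_all_equal_scores_warns_and_selects_all(self):
        with pytest.warns(UserWarning):
            out = g.select_top_quantile(_spots([0.5] * 6), "activated", 0.25)
        assert out["in_state"].all()

    def test_per_sample_thresholds(self):
        a = _spots([0.1, 0.2, 0.3, 0.9], sample="a")
        b = _spots([0.6, 0.7, 0.8, 0.95], sample="b")
        out = g.select_top_quantile(pd.concat([a, b], ignore_index=True), "activated", 0.25)
        picked = out.loc[out["in_state"], ["sample_id", "score_activated"]]
        assert set(map(tuple, picked.to_numpy())) == {("a", 0.9), ("b", 0.95)}

    @given(
        scores=st.lists(st.floats(0, 1, width=32), min_size=1, max_size=40),
        q=st.sampled_from([0.1, 0.25, 0.5, 0.75, 1.0]),
    )
    @settings(max_examples=80)
    def test_selection_count_bounds_and_monotonicity(self, scores, q):
        out = g.select_top_quantile(_spots(scores), "activated", q)
        n = len(scores)
        k = int(out["in_state"].sum())
        assert math.ceil(q * n) <= k <= n
        if q < 1.0:
            bigger = g.select_top_quantile(_spots(scores), "activated", min(1.0, q + 0.25))
            assert bigger["in_state"].sum() >= k

    def test_missing_score_column(self):
        with pytest.raises(KeyError):
            g.select_top_quantile(_spots([0.1]), "nonexistent")


class TestLayerFractions:
    def test_hand_fractions(self):
        layers = ["II"] * 10 + ["III"] * 4
        scores = [0.9, 0.8] + [0.1] * 8 + [0.2] * 4
        spots = _spots(scores, layers=layers)
        spots["in_state"] = [True, True] + [False] * 8 + [False] * 4
        frac = g.layer_state_fractions(spots, "activated").set_index("layer")
        assert frac.loc["II", "fraction"] == pytest.approx(0.2)
        assert frac.loc["III", "fraction"] == 0.0
        assert np.isnan(frac.loc["IV", "fraction"])

    @given(
        data=st.lists(
            st.tuples(st.sampled_from(["II", "III", "IV", "V", "VI"]), st.booleans()),
            min_size=1,
            max_size=60,
        )
    )
    @settings(max_examples=60)
    def test_matches_brute_force_groupby(self, data):
        layers = [d[0] for d in data]
        flags = [d[1] for d in data]
        spots = _spots([0.5] * len(data), layers=layers)
        spots["in_state"] = flags
        with pytest.warns(UserWarning) if len(set(layers)) < 5 else _nullcontext():
            frac = g.layer_state_fractions(spots, "activated").set_index("layer")
        for lay in set(layers):
            num = sum(f for l, f in data if l == lay)
            den = sum(1 for l, _ in data if l == lay)
            assert frac.loc[lay, "fraction"] == pytest.approx(num / den, abs=1e-12)


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *a):
        return False


class TestClassifyProximity:
    def test_flag_mode(self):
        spots = _spots([0.1, 0.2], ab=[True, False])
        out = g.classify_proximity(spots, "ab")
        assert out["proximity"].tolist() == ["proximal", "distal"]

    def test_distance_mode_strict_threshold(self):
        spots = _spots([0.1, 0.2])
        spots.loc[0, ["x_um", "y_um"]] = (54.0, 0.0)
        spots.loc[1, ["x_um", "y_um"]] = (56.0, 0.0)
        out = g.classify_proximity(spots, "ab", plaque_centers=[[0.0, 0.0]], radius_um=55)
        assert out["proximity"].tolist() == ["proximal", "distal"]

    def test_no_plaques_all_distal(self):
        out = g.classify_proximity(_spots([0.1] * 3), "ab", plaque_centers=np.empty((0, 2)))
        assert (out["proximity"] == "distal").all()

    def test_partition(self, spot_table):
        out = g.classify_proximity(spot_table, "ab")
        assert set(out["proximity"]) <= {"proximal", "distal"}
        assert len(out) == len(spot_table)

    def test_missing_annotation_error(self):
        spots = _spots([0.1]).drop(columns=["ab_overlap"])
        with pytest.raises(MissingAnnotationError):
            g.classify_proximity(spots, "ab")


def brute_force_chi2(table):
    """Pearson chi-square, no correction: sum (O-E)^2/E."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def _flagged_spots(table):
    """Spots realizing a 2x2 (proximal/distal x in-state/not) table."""
    rows = []
    for r, prox in enumerate([True, False]):
        for c, flag in enumerate([True, False]):
            rows.extend([(prox, flag)] * int(table[r][c]))
    spots = _spots([0.5] * len(rows), ab=[r[0] for r in rows])
    spots["in_state"] = [r[1] for r in rows]
    return g.classify_proximity(spots, "ab")


class TestEnrichmentChisq:
    def test_worked_table(self):
        res = g.enrichment_chisq(
            _flagged_spots([[30, 70], [10, 90]]), "activated", correction=False
        )
        assert res.chi2_stat == pytest.approx(12.5, abs=1e-9)
        assert res.p_value == pytest.approx(4.07e-4, rel=5e-3)
        assert res.fractions == (0.3, 0.1)

    def test_identical_fractions_null(self):
        res = g.enrichment_chisq(
            _flagged_spots([[20, 80], [20, 80]]), "activated", correction=False
        )
        assert res.chi2_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    @settings(max_examples=100)
    def test_oracle_equivalence_grid(self, a, b, c, d):
        table = [[a, b], [c, d]]
        res = g.enrichment_chisq(_flagged_spots(table), "activated", correction=False)
        assert res.chi2_stat == pytest.approx(brute_force_chi2(table), abs=1e-9)

    def test_layer_grouping(self):
        layers = ["II"] * 50 + ["V"] * 50
        spots = _spots([0.5] * 100, layers=layers)
        spots["in_state"] = [True] * 30 + [False] * 20 + [True] * 10 + [False] * 40
        res = g.enrichment_chisq(spots, "activated", "external_vs_internal", correction=False)
        assert res.contingency.tolist() == [[30, 20], [10, 40]]
        assert res.fractions == (0.6, 0.2)

    def test_low_expected_count_flagged(self):
        with pytest.warns(UserWarning):
            res = g.enrichment_chisq(_flagged_spots([[1, 1], [0, 150]]), "activated")
        assert res.low_expected_count

    def test_end_to_end_detects_configured_enrichment(self):
        cfg = g.SyntheticConfig(seed=21, activated_odds_ratio=3.0)
        spots = g.classify_proximity(g.generate_spot_table(cfg), "ab")
        flagged = g.select_top_quantile(spots, "activated")
        res = g.enrichment_chisq(flagged, "activated")
        assert res.p_value < 0.05
        assert res.fractions[0] > res.fractions[1]


def welch_t_by_hand(x, y):
    mx, my = np.mean(x), np.mean(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    nx, ny = len(x), len(y)
    t = (mx - my) / math.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return t, df


class TestStainingComparison:
    def _table(self, ext_shares, int_shares, category="P2RY12+", total=100):
        rows = []
        for i, (e, n) in enumerate(zip(ext_shares, int_shares)):
            rows.append((f"S{i}", "II-III", category, int(round(e * total))))
            rows.append((f"S{i}", "IV-VI", category, int(round(n * total))))
        return pd.DataFrame(rows, columns=["sample_id", "layer_group", "category", "count"])

    def test_shares_sum_to_one(self):
        table = self._table([0.3, 0.35], [0.7, 0.65])
        norm = g.normalize_staining(table)
        sums = norm.groupby(["sample_id", "category"])["share"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_equal_means_t_zero(self):
        table = self._table([0.4, 0.6], [0.6, 0.4])
        res = g.staining_layer_comparison(table, "P2RY12+")
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_welch(self):
        ext = [0.30, 0.35, 0.25]
        itn = [0.70, 0.65, 0.75]
        res = g.staining_layer_comparison(self._table(ext, itn), "P2RY12+")
        t, _ = welch_t_by_hand(ext, itn)
        assert res.t_stat == pytest.approx(t, abs=1e-9)
        assert res.mean_external == pytest.approx(0.3)

    def test_zero_total_sample_excluded(self):
        table = self._table([0.3, 0.35, 0.25], [0.7, 0.65, 0.75])
        table.loc[table["sample_id"] == "S0", "count"] = 0
        with pytest.warns(UserWarning):
            res = g.staining_layer_comparison(table, "P2RY12+")
        assert res.n_samples == 2

    def test_insufficient_replication(self):
        table = self._table([0.3], [0.7])
        with pytest.raises(InsufficientReplicationError):
            g.staining_layer_comparison(table, "P2RY12+")
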
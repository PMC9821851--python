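"""Welch tests, fold changes, volcano selection, autoscaling and PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from ginsenolib import seed
from ginsenolib.features import FeatureTable, MetaboliteGroup
from ginsenolib.stats import (
    autoscale,
    heatmap_matrix,
    marker_summary,
    pca_scores,
    significance_tiers,
    volcano_select,
    welch_fold,
)

N_WILD, N_CULT = 12, 19


def make_table(wild, cult):
    """FeatureTable from (features x n_wild) and (features x n_cult) arrays."""
    wild, cult = np.atleast_2d(wild), np.atleast_2d(cult)
    samples = [f"W{i:02d}" for i in range(wild.shape[1])] + [
        f"C{i:02d}" for i in range(cult.shape[1])
    ]
    groups = {s: ("wild" if s.startswith("W") else "cultivated") for s in samples}
    n = wild.shape[0]
    df = pd.DataFrame(
        {"mz": np.linspace(400, 1200, n), "rt": np.linspace(1, 80, n)},
        index=pd.Index([f"F{i:04d}" for i in range(n)], name="feature_id"),
    )
    data = np.hstack([wild, cult])
    for j, s in enumerate(samples):
        df[s] = data[:, j]
    return FeatureTable(df, groups)


class TestWelchFold:
    def test_identical_groups_give_p_one_fc_one(self):
        wild = np.tile([1.0, 3.0], 6)  # mean 2, both groups
        cult = np.concatenate([np.tile([1.0, 3.0], 9), [2.0]])
        res = welch_fold(make_table(wild, cult))
        assert res["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert res["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_type_i_error_calibrated(self, rng):
        """Null rejection rate at p<0.05 falls in the binomial 99.7% band."""
        n = 1000
        wild = rng.normal(1000, 100, size=(n, N_WILD))
        cult = rng.normal(1000, 100, size=(n, N_CULT))
        res = welch_fold(make_table(wild, cult))
        rate = float((res["p_value"] < 0.05).mean())
        half_width = 3 * np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < half_width

    def test_null_p_values_uniform(self, rng):
        """Kolmogorov-Smirnov does not reject uniformity at alpha = 0.01."""
        wild = rng.normal(1000, 100, size=(1000, N_WILD))
        cult = rng.normal(1000, 100, size=(1000, N_CULT))
        res = welch_fold(make_table(wild, cult))
        assert sps.kstest(res["p_value"], "uniform").pvalue > 0.01

    def test_planted_effect_recovered(self, rng):
        """An 8-fold effect at CV 20% and the study group sizes is found."""
        sigma = np.sqrt(np.log1p(0.2**2))
        wild = 8000 * np.exp(rng.normal(-sigma**2 / 2, sigma, size=(1, N_WILD)))
        cult = 1000 * np.exp(rng.normal(-sigma**2 / 2, sigma, size=(1, N_CULT)))
        res = welch_fold(make_table(wild, cult))
        assert res["fold_change"].iloc[0] == pytest.approx(8.0, rel=0.15)
        assert res["p_value"].iloc[0] < 0.01
        assert res["direction"].iloc[0] == "up-in-wild"

    def test_zero_mean_uses_pseudocount_and_flags(self):
        wild = np.zeros((1, 4))
        cult = np.full((1, 4), 100.0) + [[0, 1, -1, 2]]
        res = welch_fold(make_table(wild, cult))
        assert bool(res["pseudo_count_used"].iloc[0])
        assert np.isfinite(res["fold_change"].iloc[0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="wild"):
            welch_fold(make_table(np.ones((2, 1)), np.ones((2, 5)) * [[1, 2, 3, 4, 5]]))


class TestVolcanoSelect:
    @staticmethod
    def results_frame(fc_ratio, p):
        fc_ratio, p = np.asarray(fc_ratio, float), np.asarray(p, float)
        return pd.DataFrame(
            {
                "ratio_wild_over_cultivated": fc_ratio,
                "fold_change": np.maximum(fc_ratio, 1 / fc_ratio),
                "p_value": p,
            },
            index=[f"F{i}" for i in range(len(p))],
        )

    def test_boundary_values_not_selected(self):
        res = self.results_frame([2.0, 0.5, 4.0], [0.01, 0.05, 0.01])
        up_w, up_c, ns = volcano_select(res)
        assert len(up_w) == 1 and len(up_c) == 0 and len(ns) == 2

    def test_sets_disjoint_and_cover_input(self, rng):
        res = self.results_frame(np.exp(rng.normal(0, 1, 200)), rng.uniform(0, 1, 200))
        up_w, up_c, ns = volcano_select(res)
        idx = up_w.index.union(up_c.index).union(ns.index)
        assert len(up_w) + len(up_c) + len(ns) == 200
        assert idx.sort_values().equals(res.index.sort_values())

    def test_lowering_p_threshold_never_adds(self, rng):
        res = self.results_frame(np.exp(rng.normal(0, 1, 300)), rng.uniform(0, 1, 300))
        prev = None
        for p_thresh in (0.05, 0.01, 0.001):
            up_w, up_c, _ = volcano_select(res, p_thresh=p_thresh)
            selected = set(up_w.index) | set(up_c.index)
            if prev is not None:
                assert selected <= prev
            prev = selected

    def test_planted_effects_recovered(self, rng):
        """10 up + 10 down planted at strong effect among 80 nulls."""
        n_up, n_down, n_null = 10, 10, 80
        wild = np.vstack(
            [
                rng.normal(8000, 800, size=(n_up, N_WILD)),
                rng.normal(1000, 100, size=(n_down, N_WILD)),
                rng.normal(1000, 100, size=(n_null, N_WILD)),
            ]
        )
        cult = np.vstack(
            [
                rng.normal(1000, 100, size=(n_up, N_CULT)),
                rng.normal(8000, 800, size=(n_down, N_CULT)),
                rng.normal(1000, 100, size=(n_null, N_CULT)),
            ]
        )
        res = welch_fold(make_table(wild, cult))
        up_w, up_c, _ = volcano_select(res)
        planted = set(res.index[: n_up + n_down])
        recovered = (set(up_w.index) | set(up_c.index)) & planted
        false_pos = (set(up_w.index) | set(up_c.index)) - planted
        assert len(recovered) >= 18
        assert len(false_pos) <= 5


class TestSignificanceTiers:
    def test_inclusive_boundaries(self):
        res = TestVolcanoSelect.results_frame([1.5, 3.0, 1.2], [0.05, 0.001, 0.2])
        tiers = significance_tiers(res)
        assert list(tiers) == ["significant", "highly significant", "ns"]

    def test_matches_direct_threshold_oracle(self, rng):
        res = TestVolcanoSelect.results_frame(
            np.exp(rng.normal(0, 0.6, 500)), rng.uniform(0, 1, 500)
        )
        tiers = significance_tiers(res)
        sig = (res["fold_change"] >= 1.5) & (res["p_value"] <= 0.05)
        high = sig & (res["p_value"] <= 0.01)
        assert ((tiers != "ns") == sig).all()
        assert ((tiers == "highly significant") == high).all()
        # highly significant is a subset of significant
        assert set(tiers[tiers == "highly significant"].index) <= set(tiers[tiers != "ns"].index)


class TestAutoscale:
    def test_rows_standardized(self, rng):
        m = pd.DataFrame(rng.lognormal(10, 1, size=(30, 8)))
        scaled = autoscale(m)
        assert np.abs(scaled.mean(axis=1)).max() < 1e-10
        assert np.abs(scaled.std(axis=1, ddof=0) - 1).max() < 1e-10

    def test_constant_row_zeroed_with_warning(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            scaled = autoscale(m)
        assert (scaled.iloc[0] == 0).all()

    def test_idempotent(self, rng):
        m = pd.DataFrame(rng.normal(0, 5, size=(10, 6)))
        once = autoscale(m)
        twice = autoscale(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())


class TestPca:
    def test_rank_one_matrix_single_component(self, rng):
        row = rng.normal(0, 1, 10)
        m = pd.DataFrame(np.outer(rng.normal(1, 0.2, 15), row))
        scores, _, var = pca_scores(autoscale(m), n_components=3)
        assert var.iloc[0] == pytest.approx(100.0, abs=1e-6)

    def test_separated_groups_split_on_pc1(self, rng):
        wild = rng.normal(5000, 100, size=(40, N_WILD))
        cult = rng.normal(1000, 100, size=(40, N_CULT))
        table = make_table(wild, cult)
        scores, _, _ = pca_scores(autoscale(table.intensities), n_components=2)
        labels = [table.groups[s] for s in scores.index]
        assert silhouette_score(scores[["PC1"]], labels) > 0

    def test_full_reconstruction(self, rng):
        m = autoscale(pd.DataFrame(rng.normal(0, 1, size=(12, 7))))
        scores, loadings, var = pca_scores(m)
        X = m.to_numpy().T
        recon = scores.to_numpy() @ loadings.to_numpy().T + X.mean(axis=0)
        assert np.abs(recon - X).max() < 1e-8
        assert var.sum() <= 100.0 + 1e-9


class TestHeatmapMatrix:
    def test_orders_by_p_value(self):
        m = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        p = pd.Series([0.2, 0.01, 0.05], index=["a", "b", "c"])
        ordered = heatmap_matrix(m, p)
        assert list(ordered.index) == ["b", "c", "a"]

    def test_is_permutation(self, rng):
        m = pd.DataFrame(rng.normal(size=(20, 4)), index=[f"f{i}" for i in range(20)])
        p = pd.Series(rng.uniform(size=20), index=m.index)
        ordered = heatmap_matrix(m, p)
        assert sorted(ordered.index) == sorted(m.index)

    def test_ties_stable_by_feature_id(self):
        m = pd.DataFrame(np.zeros((3, 2)), index=["z", "a", "m"])
        p = pd.Series([0.5, 0.5, 0.5], index=m.index)
        assert list(heatmap_matrix(m, p).index) == ["a", "m", "z"]


class TestMarkerSummary:
    @staticmethod
    def group_for(fid, name="x", cls="PPD"):
        return MetaboliteGroup(
            compound=name, compound_class=cls, consensus_rt=10.0,
            member_ids=[fid], species={"[M-H]-"}, representative_id=fid,
        )

    def test_identical_groups_fc_one(self):
        wild = np.full((1, 4), 500.0)
        cult = np.full((1, 5), 500.0)
        table = make_table(wild, cult)
        out = marker_summary([self.group_for("F0000")], table)
        assert out["fold_change"].iloc[0] == pytest.approx(1.0)
        assert out["richer_in"].iloc[0] == "ns"

    def test_large_planted_fold_recovered(self, rng):
        sigma = np.sqrt(np.log1p(0.2**2))
        wild = 54.5 * 1e3 * np.exp(rng.normal(-sigma**2 / 2, sigma, size=(1, N_WILD)))
        cult = 1e3 * np.exp(rng.normal(-sigma**2 / 2, sigma, size=(1, N_CULT)))
        out = marker_summary([self.group_for("F0000")], make_table(wild, cult))
        assert out["fold_change"].iloc[0] == pytest.approx(54.5, rel=0.2)
        assert out["richer_in"].iloc[0] == "wild"

    def test_missing_marker_raises(self):
        table = make_table(np.ones((1, 4)), np.ones((1, 5)))
        with pytest.raises(KeyError, match="nope"):
            marker_summary([self.group_for("nope")], table)

    def test_marker_direction_labels(self):
        """The curated marker set favors wild for 5 and cultivated for 6."""
        directions = [e.richer_in for e in seed.GINSENOSIDE_MARKERS]
        assert directions.count("wild") == 5
        assert directions.count("cultivated") == 6
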
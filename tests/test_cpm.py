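"""Partial Spearman selection, LOOCV prediction, permutation inference,
consensus networks and degree accounting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from gazecpm.connectivity import ConnectivityMatrix
from gazecpm.cpm import (
    CANONICAL_NETWORKS,
    CanonicalAtlas,
    CPMConfig,
    consensus_network,
    degree_summary,
    loocv_predict,
    network_strength,
    partial_spearman,
    permutation_test,
    select_edges,
    top_nodes,
)

from _oracles import naive_cpm_loocv, naive_partial_spearman


class TestPartialSpearman:
    def test_reduces_to_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(0)
        e, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        assert partial_spearman(e, b) == pytest.approx(st.spearmanr(e, b).statistic)

    def test_monotone_relation_gives_one(self):
        e = np.array([0.1, 0.5, 1.2, 3.0, 7.0, 9.0])
        assert partial_spearman(e, np.exp(e)) == pytest.approx(1.0)

    def test_eight_subject_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        e = rng.normal(0, 1, 8)
        b = 0.5 * e + rng.normal(0, 1, 8)
        c = rng.normal(0, 1, (8, 1))
        assert partial_spearman(e, b, c) == pytest.approx(
            naive_partial_spearman(e, b, c), abs=1e-12
        )

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(10), np.arange(10.0))

    def test_too_few_subjects_for_covariates_is_error(self):
        with pytest.raises(ValueError):
            partial_spearman(np.arange(4.0), np.arange(4.0), np.ones((4, 2)))


class TestEdgeSelection:
    def test_strict_cut(self):
        pos, neg = select_edges(np.array([0.35, -0.31, 0.30, -0.29]), 0.3)
        assert pos.tolist() == [0] and neg.tolist() == [1]

    def test_all_below_threshold(self):
        pos, neg = select_edges(np.array([0.1, -0.2]), 0.3)
        assert len(pos) == 0 and len(neg) == 0

    def test_zero_threshold_splits_by_sign(self):
        pos, neg = select_edges(np.array([0.01, -0.01, 0.5]), 0.0)
        assert pos.tolist() == [0, 2] and neg.tolist() == [1]


class TestNetworkStrength:
    def test_empty_set_is_zero(self):
        assert network_strength(np.array([0.2, 0.3]), np.array([], dtype=int)) == 0.0

    def test_sum_over_edges(self):
        assert network_strength(np.array([0.2, 0.3, 9.0]), np.array([0, 1])) == pytest.approx(0.5)

    def test_additivity_over_partition(self):
        rng = np.random.default_rng(1)
        vec = rng.normal(0, 1, 50)
        edges = rng.choice(50, 20, replace=False)
        total = network_strength(vec, edges)
        part = network_strength(vec, edges[:7]) + network_strength(vec, edges[7:])
        assert total == pytest.approx(part)

    def test_matrix_input_uses_upper_triangle(self):
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = 0.4
        mat = ConnectivityMatrix(z=z, node_ids=np.arange(3), n_volumes_used=10)
        assert network_strength(mat, np.array([0])) == pytest.approx(0.4)

    def test_out_of_range_edge_is_error(self):
        with pytest.raises(ValueError):
            network_strength(np.zeros(3), np.array([5]))


class TestLOOCV:
    def test_exact_linear_recovery(self):
        """Behavior an exact linear function of one edge's z: that edge is
        selected in every fold and predictions equal observations."""
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (12, 6))
        y = 2.0 + 1.5 * X[:, 3]
        # a high cut keeps chance-correlated noise edges out, so every fold
        # selects exactly the signal edge (its Spearman rho with y is 1)
        res = loocv_predict(X, y, None, CPMConfig(selection_threshold=0.95, seed=0))
        assert all(sel.tolist() == [3] for sel in res.fold_edges["pos"])
        assert np.allclose(res.predictions["pos"], y, atol=1e-9)
        assert res.accuracy["pos"] == pytest.approx(1.0)

    def test_matches_naive_fold_by_fold_oracle(self, toy_cpm_data):
        X, y, C = toy_cpm_data
        res = loocv_predict(X, y, C, CPMConfig(seed=0))
        folds, preds = naive_cpm_loocv(X, y, C, 0.3)
        for sign in ("pos", "neg"):
            assert np.allclose(res.predictions[sign], preds[sign], atol=1e-10)
            for a, b in zip(res.fold_edges[sign], folds[sign]):
                assert a.tolist() == b.tolist()

    def test_null_data_accuracy_near_zero(self):
        rng = np.random.default_rng(3)
        accs = []
        for rep in range(12):
            X = rng.normal(0, 1, (20, 40))
            y = rng.normal(0, 1, 20)
            res = loocv_predict(X, y, None, CPMConfig(seed=rep))
            if not np.isnan(res.accuracy["pos"]):
                accs.append(res.accuracy["pos"])
        assert abs(np.mean(accs)) < 0.35

    def test_fold_independence_of_held_out_subject(self, toy_cpm_data):
        """Corrupting the held-out subject's matrix must not change that
        fold's training selections."""
        X, y, C = toy_cpm_data
        res = loocv_predict(X, y, C, CPMConfig(seed=0))
        X2 = X.copy()
        X2[5] = 1e6  # absurd values for subject 5
        res2 = loocv_predict(X2, y, C, CPMConfig(seed=0))
        for sign in ("pos", "neg"):
            assert res.fold_edges[sign][5].tolist() == res2.fold_edges[sign][5].tolist()

    def test_too_few_subjects_is_error(self):
        with pytest.raises(ValueError):
            loocv_predict(np.zeros((5, 3)), np.zeros(5), None, CPMConfig())

    def test_empty_selection_predicts_training_mean(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1e-3, (12, 4))
        y = rng.normal(0, 1, 12)
        cfg = CPMConfig(selection_threshold=0.999)
        with pytest.warns(UserWarning):
            res = loocv_predict(X, y, None, cfg)
        for i in range(12):
            assert res.predictions["pos"][i] == pytest.approx(np.delete(y, i).mean())


class TestPermutationTest:
    def test_deterministic_given_seed(self, toy_cpm_data, cpm_config):
        X, y, C = toy_cpm_data
        a = permutation_test(X, y, C, cpm_config)
        b = permutation_test(X, y, C, cpm_config)
        assert a.permutation_p == b.permutation_p
        assert np.array_equal(a.null_accuracy["pos"], b.null_accuracy["pos"])

    def test_strong_signal_gives_zero_p(self, toy_cpm_data, cpm_config):
        X, y, C = toy_cpm_data
        res = permutation_test(X, y, C, cpm_config)
        assert res.permutation_p["pos"] == 0.0
        cfg2 = CPMConfig(n_permutations=50, seed=11, add_one_smoothing=True)
        res2 = permutation_test(X, y, C, cfg2)
        assert res2.permutation_p["pos"] == pytest.approx(1 / 51)

    def test_p_one_when_observed_ties_all_permutations(self):
        """If every permuted accuracy >= observed, the plain proportion is 1."""
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (12, 5))
        y = rng.normal(0, 1, 12)
        res = permutation_test(X, y, None, CPMConfig(n_permutations=30, seed=0))
        obs = res.accuracy["pos"]
        count = int(np.count_nonzero(res.null_accuracy["pos"] >= obs))
        assert res.permutation_p["pos"] == pytest.approx(count / 30)
        if count == 30:
            assert res.permutation_p["pos"] == 1.0


class TestConsensusAndDegrees:
    def test_fold_fraction_rule(self):
        sets = [np.array([0, 1])] * 46 + [np.array([1])]
        cons = consensus_network(sets, 0.9, n_edges=3)
        assert cons.tolist() == [0, 1]  # 46/47 ~ 0.979 for edge 0

    def test_half_selected_excluded_at_90(self):
        sets = [np.array([2])] * 10 + [np.array([], dtype=int)] * 10
        assert consensus_network(sets, 0.9, 4).tolist() == []

    def test_fraction_one_is_intersection(self):
        sets = [np.array([0, 1]), np.array([0, 2]), np.array([0, 1, 2])]
        assert consensus_network(sets, 1.0, 3).tolist() == [0]

    def test_degree_accounting_handshake_and_paircounts(self):
        rng = np.random.default_rng(0)
        n_nodes, n_edges = 220, 1210
        edges = rng.choice(24_090, n_edges, replace=False)
        atlas = CanonicalAtlas.blocks(n_nodes)
        nodes, pair = degree_summary(edges, n_nodes, atlas)
        assert nodes["degree"].sum() == 2 * n_edges
        assert pair.to_numpy().sum() == n_edges
        assert np.allclose(nodes["degree_proportion"], nodes["degree"] / n_edges)

    def test_degree_24_of_1210_prints_0_020(self):
        # a node with 24 incident consensus edges in a 1210-edge network
        edges = np.arange(24).tolist()  # node 0 paired with nodes 1..24
        extra = np.arange(219 + 100, 219 + 100 + 1186)  # edges not touching node 0
        nodes, _ = degree_summary(np.array(edges + extra.tolist()), 220, None)
        assert nodes["degree"].iloc[0] == 24
        assert round(float(nodes["degree_proportion"].iloc[0]), 3) == 0.020

    def test_top_nodes_count_and_ties(self):
        df = pd.DataFrame(
            {"node": np.arange(220), "network": "MF", "degree": np.arange(220)[::-1],
             "degree_proportion": 0.0}
        )
        top = top_nodes(df, 0.10)
        assert len(top) == 22
        df2 = df.copy()
        df2["degree"] = 5  # everything tied
        with pytest.warns(UserWarning):
            top2 = top_nodes(df2, 0.10)
        assert len(top2) == 220

    def test_atlas_rejects_unknown_labels(self):
        with pytest.raises(ValueError):
            CanonicalAtlas(labels=np.array(["XX"] * 3, dtype=object))
        assert set(CanonicalAtlas.blocks(50).labels) <= set(CANONICAL_NETWORKS)
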
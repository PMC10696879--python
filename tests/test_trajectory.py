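import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import hashatac as ha
from hashatac._stats import fit_negative_binomial, natural_spline_basis
from hashatac.io import LabeledMatrix
from hashatac.trajectory import (PrincipalGraph, aggregate_groups,
                                 compute_pseudodose, fit_frip_interaction,
                                 learn_principal_graph, smooth_and_classify)

from conftest import irls_glm


class TestPrincipalGraph:
    def test_two_clusters_one_edge(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (50, 2)),
                       rng.normal(5, 0.1, (50, 2))])
        g = learn_principal_graph(X, n_centroids=2, seed=0)
        assert g.graph.number_of_edges() == 1

    def test_line_gives_path_mst(self):
        # cells on a 1-D line: the MST over centroids must be a path
        x = np.linspace(0, 10, 200).reshape(-1, 1)
        X = np.hstack([x, np.zeros_like(x)])
        g = learn_principal_graph(X, n_centroids=8, seed=0)
        degrees = sorted(d for _, d in g.graph.degree())
        assert degrees == [1, 1] + [2] * 6
        # brute-force MST total weight equals the returned one
        from itertools import combinations

        import networkx as nx

        full = nx.Graph()
        for i, j in combinations(range(len(g.nodes)), 2):
            full.add_edge(i, j, weight=float(np.linalg.norm(
                g.nodes[i] - g.nodes[j])))
        ref = nx.minimum_spanning_tree(full)
        assert sum(d["weight"] for *_, d in g.graph.edges(data=True)) == \
            pytest.approx(sum(d["weight"] for *_, d in ref.edges(data=True)))

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 3))
        a = learn_principal_graph(X, 10, seed=4)
        b = learn_principal_graph(X, 10, seed=4)
        assert np.array_equal(a.assignment, b.assignment)
        assert np.allclose(a.nodes, b.nodes)

    def test_degenerate_embedding_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            learn_principal_graph(np.ones((50, 2)), 5)


def path_graph(lengths):
    """Hand-built path graph A-B-C... with given edge lengths."""
    import networkx as nx

    g = nx.Graph()
    for i, w in enumerate(lengths):
        g.add_edge(i, i + 1, weight=w)
    n_nodes = len(lengths) + 1
    nodes = np.zeros((n_nodes, 2))
    return g, n_nodes


class TestPseudodose:
    def test_path_distance(self):
        g, n_nodes = path_graph([1.0, 2.0])
        pg = PrincipalGraph(nodes=np.zeros((n_nodes, 2)), graph=g,
                            assignment=np.array([0, 1, 2]))
        # cell 0 vehicle at node A -> root; cell at C has psi = 3
        out = compute_pseudodose(pg, [True, False, False], k_bins=3)
        assert out["psi"].tolist() == [0.0, 1.0, 3.0]

    def test_root_cells_have_zero(self):
        g, n_nodes = path_graph([2.0])
        pg = PrincipalGraph(np.zeros((n_nodes, 2)), g,
                            np.array([0, 0, 1]))
        out = compute_pseudodose(pg, [True, True, False], k_bins=2)
        assert (out.loc[[0, 1], "psi"] == 0).all()

    def test_exact_kmeans_bins(self):
        g, n_nodes = path_graph([5.0])
        pg = PrincipalGraph(np.zeros((n_nodes, 2)), g,
                            np.array([0, 0, 0, 1, 1, 1]))
        out = compute_pseudodose(pg, [True] * 3 + [False] * 3, k_bins=2)
        assert sorted(out["psi_bin_mean"].unique()) == [0.0, 5.0]

    def test_no_vehicle_majority_errors(self):
        g, n_nodes = path_graph([1.0])
        pg = PrincipalGraph(np.zeros((n_nodes, 2)), g, np.array([0, 1]))
        with pytest.raises(ValueError, match="majority-vehicle"):
            compute_pseudodose(pg, [False, False])

    def test_rotation_invariance(self, trajectory_dataset):
        _, tj = trajectory_dataset
        emb = ha.tfidf_lsi(tj.matrix, dims=6).embedding_
        theta = 0.7
        d = emb.shape[1]
        R = np.eye(d)
        R[:2, :2] = [[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]]
        veh = tj.design["vehicle"].to_numpy()
        p1 = ha.PrincipalGraphTrajectory(seed=0).fit(emb, veh).pseudodose_
        p2 = ha.PrincipalGraphTrajectory(seed=0).fit(emb @ R, veh).pseudodose_
        np.testing.assert_allclose(p1["psi"], p2["psi"], atol=1e-6)


class TestAggregation:
    def fake_pseudodose(self, psi, bins):
        return pd.DataFrame({"psi": psi, "bin": bins,
                             "psi_bin_mean": psi})

    def rand_matrix(self, n, m=20, seed=0):
        rng = np.random.default_rng(seed)
        return LabeledMatrix(
            sp.csr_matrix((rng.random((n, m)) < 0.3).astype(np.int8)),
            [f"c{i}" for i in range(n)], [f"p{j}" for j in range(m)])

    def test_even_split_within_bounds(self):
        m = self.rand_matrix(120)
        ps = self.fake_pseudodose(np.linspace(0, 1, 120), np.zeros(120, int))
        agg = aggregate_groups(m, ps)
        assert list(agg.sizes) == [60, 60]

    def test_small_bin_merged(self):
        m = self.rand_matrix(140)
        bins = np.r_[np.zeros(40, int), np.ones(100, int)]
        ps = self.fake_pseudodose(np.linspace(0, 1, 140), bins)
        agg = aggregate_groups(m, ps)
        assert agg.sizes.sum() == 140
        assert (agg.sizes >= 50).all() and (agg.sizes <= 100).all()

    def test_count_equals_group_size_for_ubiquitous_peak(self):
        m = self.rand_matrix(60)
        dense = m.matrix.toarray()
        dense[:, 0] = 1
        m = LabeledMatrix(sp.csr_matrix(dense), m.row_names, m.col_names)
        ps = self.fake_pseudodose(np.linspace(0, 1, 60), np.zeros(60, int))
        agg = aggregate_groups(m, ps)
        assert (agg.A[0] == agg.sizes).all()

    def test_too_few_cells_rejected(self):
        m = self.rand_matrix(30)
        ps = self.fake_pseudodose(np.linspace(0, 1, 30), np.zeros(30, int))
        with pytest.raises(ValueError):
            aggregate_groups(m, ps)


class TestSmoothClassify:
    def synthetic_agg(self, shape="up", n_groups=30, seed=0):
        rng = np.random.default_rng(seed)
        psi = np.linspace(0, 1, n_groups)
        size = np.full(n_groups, 60)
        if shape == "up":
            rate = 0.1 + 0.8 * psi
        elif shape == "down":
            rate = 0.9 - 0.8 * psi
        else:
            rate = 0.1 + 0.8 * np.exp(-(psi - 0.5) ** 2 / 0.02)
        A = rng.binomial(60, rate).reshape(1, -1).astype(float)
        from hashatac.trajectory import AggregateAccessibility

        return AggregateAccessibility(
            A=A, psi=psi, S=np.full(n_groups, 30.0) + rng.normal(
                0, 0.5, n_groups),
            sizes=size, peak_names=["pk"], groups=[np.arange(2)] * n_groups)

    @pytest.mark.parametrize("shape,expected", [
        ("up", "opening"), ("down", "closing"), ("bump", "dynamic")])
    def test_trend_rule(self, shape, expected):
        agg = self.synthetic_agg(shape)
        out = smooth_and_classify(agg, {"pk"})
        assert out.loc["pk", "trend_class"] == expected

    def test_non_da_peak_is_static(self):
        agg = self.synthetic_agg("up")
        out = smooth_and_classify(agg, set())
        assert out.loc["pk", "trend_class"] == "static"

    def test_planted_trends_recovered(self, trajectory_dataset):
        _, tj = trajectory_dataset
        emb = ha.tfidf_lsi(tj.matrix, dims=10).embedding_
        est = ha.PrincipalGraphTrajectory(seed=0).fit(
            emb, tj.design["vehicle"].to_numpy())
        agg = aggregate_groups(tj.matrix, est.pseudodose_)
        truth = tj.truth.trend_class
        da = set(truth[truth != "static"].index)
        out = smooth_and_classify(agg, da)
        nonstatic = truth[truth != "static"]
        acc = (out.loc[nonstatic.index, "trend_class"]
               == nonstatic).mean()
        assert acc >= 0.9

    def test_nb_fixed_alpha_matches_irls_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(30, 60)
            x = rng.uniform(0, 1, n)
            B, _ = natural_spline_basis(x, df=3)
            X = np.column_stack([np.ones(n), B])
            mu = np.exp(1.0 + 0.8 * x)
            alpha = 0.3
            y = rng.negative_binomial(1 / alpha,
                                      1 / (1 + alpha * mu))
            if y.sum() == 0:
                continue
            res = fit_negative_binomial(y, X, alpha=alpha, tol=1e-14,
                                        maxiter=300)
            ref, _ = irls_glm(y, X, ("negbin", alpha), n_iter=500,
                              tol=1e-14)
            np.testing.assert_allclose(res.params, ref, atol=1e-6)


class TestFripInteraction:
    def test_constant_dose_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_frip_interaction([0.5, 0.6], [0.1, 0.2], [1.0, 1.0])

    def test_nesting_inequality(self):
        rng = np.random.default_rng(0)
        n = 300
        psi = rng.uniform(0, 1, n)
        d = rng.choice([0.0, 1.0], n)
        frip = 0.5 + 0.05 * psi * d + rng.normal(0, 0.04, n)
        res = fit_frip_interaction(frip, psi, d)
        assert res.full_llf >= res.reduced_llf
        assert res.df == 3

    def test_planted_interaction_detected(self, trajectory_dataset):
        _, tj = trajectory_dataset
        res = fit_frip_interaction(tj.frip, tj.psi_true,
                                   tj.design["d"].to_numpy())
        assert res.p < 0.05

    def test_null_interaction_calibrated(self):
        # type-I at nominal 0.05 within [0.03, 0.07] over 500 simulations
        rng = np.random.default_rng(42)
        n = 300
        psi = rng.uniform(0, 1, n)
        d = rng.choice([0.0, 0.5, 1.0], n)
        rej = 0
        reps = 500
        for _ in range(reps):
            frip = 0.5 + 0.1 * psi + rng.normal(0, 0.04, n)
            rej += fit_frip_interaction(frip, psi, d).p < 0.05
        assert 0.03 <= rej / reps <= 0.07
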
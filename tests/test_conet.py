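import numpy as np
import pandas as pd
import pytest

from microdelta.core_io import FeatureTable
from microdelta.conet import (
    CoNetwork,
    CorrelationEstimate,
    DifferentialModularity,
    LouvainPartition,
    SparCC,
    build_network,
    differential_modularity,
    differential_network,
    edge_pvalues,
    hub_ranking,
    louvain_partition,
    sparcc,
)
from oracles import exhaustive_best_objective


def _compositional_counts(rng, latent, depth=5000):
    basis = np.exp(latent)
    frac = basis / basis.sum(axis=1, keepdims=True)
    return np.vstack([rng.multinomial(depth, f) for f in frac])


def _table(counts):
    return FeatureTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(counts.shape[0])],
        columns=[f"f{j}" for j in range(counts.shape[1])]))


class TestSparcc:
    def test_rho_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        est = SparCC(n_resample=5, random_state=0).fit(
            rng.integers(1, 100, (30, 8)))
        assert np.allclose(est.rho_, est.rho_.T)
        assert np.allclose(np.diag(est.rho_), 1.0)
        assert np.abs(est.rho_).max() <= 1.0

    def test_under_determined_system_rejected(self):
        with pytest.raises(ValueError, match="4 features"):
            SparCC().fit(np.ones((10, 3)))

    def test_planted_basis_correlation_recovered(self):
        rng = np.random.default_rng(1)
        lat = rng.normal(0, 1, (500, 20))
        z = rng.normal(0, 1, 500)
        lat[:, 3] = np.sqrt(0.8) * z + np.sqrt(0.2) * lat[:, 3]
        lat[:, 7] = np.sqrt(0.8) * z + np.sqrt(0.2) * lat[:, 7]
        counts = _compositional_counts(rng, lat)
        est = SparCC(random_state=1).fit(counts)
        assert est.rho_[3, 7] == pytest.approx(0.8, abs=0.15)

    def test_null_noise_tracks_correlation_oracle(self):
        """SparCC's max null |rho| should sit within noise of the oracle
        (Pearson correlation of the true basis logs), not above it."""
        gaps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            lat = rng.normal(0, 1, (500, 20))
            counts = _compositional_counts(rng, lat)
            c = np.corrcoef(lat, rowvar=False)
            np.fill_diagonal(c, 0)
            r = SparCC(n_resample=10, random_state=seed).fit(counts).rho_.copy()
            np.fill_diagonal(r, 0)
            gaps.append(np.abs(r).max() - np.abs(c).max())
        assert np.mean(gaps) < 0.03

    def test_approximate_per_sample_scale_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(50, 500, (100, 10)).astype(float)
        r1 = SparCC(n_resample=0).fit(counts).rho_
        r2 = SparCC(n_resample=0).fit(counts * 10).rho_
        assert np.abs(r1 - r2).max() < 0.1   # exact up to the pseudocount


class TestEdgePvalues:
    def _estimate(self, seed=3, n=80, d=6, n_perm=99):
        rng = np.random.default_rng(seed)
        lat = rng.normal(0, 1, (n, d))
        lat[:, 1] = 0.95 * lat[:, 0] + np.sqrt(1 - 0.95**2) * lat[:, 1]
        counts = _compositional_counts(rng, lat)
        table = _table(counts)
        est = sparcc(table, n_resample=5, seed=seed)
        return table, edge_pvalues(table, est, n_perm=n_perm, seed=seed,
                                   sparcc_kwargs={"n_resample": 5})

    def test_permutation_p_respects_pseudocount_bound(self):
        _, est = self._estimate()
        off = ~np.eye(len(est.feature_ids), dtype=bool)
        assert (est.p_sparcc[off] >= 1 / 100).all()

    def test_planted_pair_attains_minimum_p(self):
        _, est = self._estimate()
        assert est.p_sparcc[0, 1] == pytest.approx(1 / 100)
        assert est.p_pearson[0, 1] < 0.001
        assert est.p_spearman[0, 1] < 0.001


class TestBuildNetwork:
    @staticmethod
    def _estimate(p_sp, p_pe, p_sp2, rho=0.5, r_pe=0.5, r_spear=0.5):
        d = 2
        ids = ["x", "y"]
        def mat(v, diag):
            m = np.full((d, d), v)
            np.fill_diagonal(m, diag)
            return m
        return CorrelationEstimate(
            feature_ids=ids,
            rho=mat(rho, 1.0),
            basis_variances=np.ones(d),
            logratio_variances=mat(0.1, 0.0),
            r_pearson=mat(r_pe, 1.0),
            r_spearman=mat(r_spear, 1.0),
            p_sparcc=mat(p_sp, 0.0),
            p_pearson=mat(p_pe, 0.0),
            p_spearman=mat(p_sp2, 0.0),
            n_perm=999,
        )

    def test_conjunction_rule_one_method_fails(self):
        net = build_network(self._estimate(0.0005, 0.0005, 0.002))
        assert not net.edges["significant"].iloc[0]

    def test_sign_agreement_required(self):
        net = build_network(self._estimate(0.0005, 0.0005, 0.0005,
                                           r_spear=-0.4))
        assert not net.edges["significant"].iloc[0]

    def test_all_significant_same_sign(self):
        net = build_network(self._estimate(0.0005, 0.0005, 0.0005))
        assert net.edges["significant"].iloc[0]

    def test_significance_monotone_in_threshold(self):
        est = self._estimate(0.0005, 0.008, 0.0005)
        loose = build_network(est, p_threshold=0.01).edges["significant"].sum()
        tight = build_network(est, p_threshold=0.001).edges["significant"].sum()
        assert tight <= loose
        assert loose == 1 and tight == 0

    def test_unattainable_threshold_rejected(self):
        est = self._estimate(0.0005, 0.0005, 0.0005)
        est.n_perm = 99
        with pytest.raises(ValueError, match="n_perm"):
            build_network(est, p_threshold=0.001)

    def test_missing_pvalues_rejected(self):
        est = self._estimate(0.0005, 0.0005, 0.0005)
        est.p_spearman = None
        with pytest.raises(ValueError, match="p_spearman"):
            build_network(est)


class TestDifferentialNetwork:
    @staticmethod
    def _est(rho_offdiag, ids=("x", "y")):
        d = len(ids)
        rho = np.full((d, d), rho_offdiag)
        np.fill_diagonal(rho, 1.0)
        return CorrelationEstimate(
            feature_ids=list(ids), rho=rho,
            basis_variances=np.ones(d),
            logratio_variances=np.zeros((d, d)))

    def test_identical_estimates_give_empty_network(self):
        net = differential_network(self._est(0.4), self._est(0.4))
        assert net.edges.empty

    def test_positive_difference_kept_with_weight(self):
        net = differential_network(self._est(0.6), self._est(0.2))
        assert net.edges.iloc[0]["weight"] == pytest.approx(0.4)
        assert net.edges.iloc[0]["udca_sign"] == 1.0

    def test_negative_difference_dropped(self):
        net = differential_network(self._est(0.2), self._est(0.6))
        assert net.edges.empty

    def test_abs_mode_uses_magnitudes(self):
        net = differential_network(self._est(-0.6), self._est(0.2))
        assert net.edges.iloc[0]["weight"] == pytest.approx(0.4)
        assert net.edges.iloc[0]["udca_sign"] == -1.0

    def test_mismatched_nodes_error(self):
        with pytest.raises(ValueError, match="node"):
            differential_network(self._est(0.5), self._est(0.5, ids=("x", "z")))


def _net_from_adjacency(a, ids=None):
    ids = ids or [f"n{i}" for i in range(a.shape[0])]
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if a[i, j] != 0:
                rows.append({"node_i": ids[i], "node_j": ids[j],
                             "weight": a[i, j]})
    return CoNetwork(ids, pd.DataFrame(
        rows, columns=["node_i", "node_j", "weight"]))


class TestLouvain:
    def test_two_disconnected_triangles(self):
        a = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            a[i, j] = a[j, i] = 1.0
        res = louvain_partition(_net_from_adjacency(a), seed=0)
        assert res.objective == pytest.approx(0.5)
        assert res.n_modules() == 2
        assert res.contributions.sum() == pytest.approx(0.5)

    def test_single_clique_one_module(self):
        a = 1.0 - np.eye(5)
        res = louvain_partition(_net_from_adjacency(a), seed=0)
        assert res.n_modules() == 1

    def test_empty_network_singletons(self):
        a = np.zeros((4, 4))
        res = louvain_partition(_net_from_adjacency(a), seed=0)
        assert res.n_modules() == 4
        assert res.objective == 0.0

    def test_negative_weights_rejected(self):
        a = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError, match="non-negative"):
            louvain_partition(_net_from_adjacency(a))

    def test_matches_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            a = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
            a = np.triu(a, 1)
            a = a + a.T
            if a.sum() == 0:
                continue
            est = LouvainPartition(random_state=1).fit(a)
            best = exhaustive_best_objective(est.b_matrix_)
            assert est.modularity_ >= 0.95 * best - 1e-12

    def test_agrees_with_networkx_louvain(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        n = 24
        a = (rng.random((n, n)) < 0.15).astype(float)
        a = np.triu(a, 1); a = a + a.T
        est = LouvainPartition(random_state=0).fit(a)
        g = nx.from_numpy_array(a)
        comms = nx.community.louvain_communities(g, seed=0)
        q_nx = nx.community.modularity(g, comms)
        assert est.modularity_ >= q_nx - 0.03


class TestDifferentialModularity:
    def test_self_comparison_equals_weighted_modularity(self):
        rng = np.random.default_rng(1)
        a = rng.random((10, 10)) * (rng.random((10, 10)) < 0.4)
        a = np.triu(a, 1); a = a + a.T
        lp = LouvainPartition(random_state=0).fit(a)
        dm = DifferentialModularity(random_state=0).fit(a, a)
        assert dm.objective_ == pytest.approx(lp.modularity_, abs=1e-9)

    def test_matches_exhaustive_optimum_on_small_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(4, 9))
            def rnd():
                m = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
                m = np.triu(m, 1)
                return m + m.T
            ab, ap = rnd(), rnd()
            if ab.sum() == 0 or ap.sum() == 0:
                continue
            dm = DifferentialModularity(random_state=3).fit(ab, ap)
            best = exhaustive_best_objective(dm.b_matrix_)
            assert dm.objective_ >= 0.95 * best - 1e-12

    def test_planted_perturbed_module_tops_contributions(self):
        rng = np.random.default_rng(3)
        n = 12
        base = (rng.random((n, n)) < 0.2) * rng.random((n, n)) * 0.3
        base = np.triu(base, 1); base = base + base.T
        pert = base.copy()
        for i in range(4):
            for j in range(i + 1, 4):
                pert[i, j] = pert[j, i] = 0.9   # module present only perturbed
        ids = [f"n{i}" for i in range(n)]
        res = differential_modularity(
            _net_from_adjacency(base, ids), _net_from_adjacency(pert, ids),
            seed=0)
        top4 = set(res.ranking().index[:4])
        assert top4 == {"n0", "n1", "n2", "n3"}
        # contributions partition the objective across nodes
        assert res.contributions.sum() == pytest.approx(res.objective)

    def test_empty_edge_set_rejected(self):
        a = np.zeros((4, 4))
        b = np.eye(4)
        with pytest.raises(ValueError, match="empty"):
            DifferentialModularity().fit(a, b - np.eye(4))


class TestHubRanking:
    def test_star_center_ranks_first(self):
        a = np.zeros((5, 5))
        a[0, 1:] = a[1:, 0] = 0.5
        ranks = hub_ranking(_net_from_adjacency(a))
        assert ranks.index[0] == "n0"
        assert ranks.iloc[0] == pytest.approx(2.0)

    def test_strengths_match_hand_sums_on_toy(self):
        # 4-node toy: edges (0,1)=0.5, (1,2)=-0.25, (2,3)=1.0
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.5
        a[1, 2] = a[2, 1] = -0.25
        a[2, 3] = a[3, 2] = 1.0
        ranks = hub_ranking(_net_from_adjacency(a))
        assert ranks["n2"] == pytest.approx(1.25)
        assert ranks["n1"] == pytest.approx(0.75)
        assert ranks["n3"] == pytest.approx(1.0)
        assert ranks["n0"] == pytest.approx(0.5)

    def test_invariant_to_edge_enumeration_order(self):
        rng = np.random.default_rng(4)
        a = rng.random((6, 6)); a = np.triu(a, 1); a = a + a.T
        net = _net_from_adjacency(a)
        shuffled = CoNetwork(net.feature_ids,
                             net.edges.sample(frac=1, random_state=0)
                             .reset_index(drop=True))
        pd.testing.assert_series_equal(hub_ranking(net), hub_ranking(shuffled))
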
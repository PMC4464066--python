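"""Correlation matrices, shrinkage, partial correlations and networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mwasnet import (
    CorrelationMatrix,
    FeatureTable,
    ModuleSpec,
    SimConfig,
    TargetQuery,
    build_association_network,
    cor_to_pcor,
    pattern_similarity,
    sample_correlation_matrix,
    shrink_correlation,
    simulate_feature_table,
    stringency_sweep,
)


def _gaussian_table(R, n, seed, mz0=200.0):
    """Feature table whose log10 intensities realize correlation matrix R."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R)
    Z = L @ rng.standard_normal((R.shape[0], n))
    X = 10.0 ** (5.0 + 0.5 * Z)
    return FeatureTable(
        mz=mz0 + 10.0 * np.arange(R.shape[0]),
        rt=np.full(R.shape[0], 100.0),
        intensities=X,
        sample_ids=[f"s{j}" for j in range(n)],
    )


def first_order_pcor(r12, r13, r23):
    """Closed-form partial correlation of variables 1,2 given 3."""
    return (r12 - r13 * r23) / np.sqrt((1 - r13 ** 2) * (1 - r23 ** 2))


class TestSampleCorrelationMatrix:
    def test_duplicated_feature_gives_unit_offdiagonal(self):
        t = _gaussian_table(np.eye(2), 40, seed=0)
        X = np.vstack([t.intensities, t.intensities[0:1, :]])
        t2 = FeatureTable(mz=[100.0, 110.0, 120.0], rt=[1.0, 2.0, 3.0],
                          intensities=X, sample_ids=t.sample_ids)
        R = sample_correlation_matrix(t2, [0, 1, 2])
        assert R.values[0, 2] == pytest.approx(1.0)

    def test_independent_features_near_zero(self):
        t = _gaussian_table(np.eye(2), 1000, seed=1)
        R = sample_correlation_matrix(t, [0, 1])
        assert abs(R.values[0, 1]) < 0.1

    def test_subset_of_one_rejected(self, toy_table):
        with pytest.raises(ValueError):
            sample_correlation_matrix(toy_table, [0])

    def test_symmetric_unit_diagonal(self):
        t = _gaussian_table(np.eye(4), 60, seed=2)
        R = sample_correlation_matrix(t, [0, 1, 2, 3])
        np.testing.assert_allclose(R.values, R.values.T)
        np.testing.assert_allclose(np.diag(R.values), 1.0)


class TestShrinkCorrelation:
    def test_all_zero_offdiagonals_give_lambda_one(self):
        # orthogonalized columns -> sample correlations exactly 0
        rng = np.random.default_rng(3)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        a = a - a.mean()
        b = b - b.mean()
        b = b - (a @ b) / (a @ a) * a  # exact orthogonal residual
        X = 10.0 ** np.vstack([5 + a, 5 + b])
        t = FeatureTable(mz=[100.0, 200.0], rt=[1.0, 2.0], intensities=X,
                         sample_ids=[f"s{j}" for j in range(20)])
        R = shrink_correlation(t, [0, 1])
        assert R.shrinkage == pytest.approx(1.0)
        np.testing.assert_allclose(R.values, np.eye(2), atol=1e-12)

    def test_lambda_in_unit_interval(self):
        t = _gaussian_table(np.eye(6), 25, seed=4)
        R = shrink_correlation(t, range(6))
        assert 0.0 <= R.shrinkage <= 1.0

    def test_lambda_zero_equals_sample_matrix_exactly(self):
        t = _gaussian_table(np.eye(5), 40, seed=5)
        Rs = shrink_correlation(t, range(5), shrinkage=0.0)
        R = sample_correlation_matrix(t, range(5))
        np.testing.assert_allclose(Rs.values, R.values, atol=1e-12)

    def test_strong_structure_shrinks_little(self):
        # planted structure, n=500, p=10: lambda < 0.1 and near-sample output
        R0 = 0.6 * np.ones((10, 10))
        np.fill_diagonal(R0, 1.0)
        t = _gaussian_table(R0, 500, seed=6)
        Rs = shrink_correlation(t, range(10))
        R = sample_correlation_matrix(t, range(10))
        assert Rs.shrinkage < 0.1
        assert np.max(np.abs(Rs.values - R.values)) < 0.05

    def test_lambda_matches_direct_formula(self):
        """Independent recomputation of the Schafer-Strimmer intensity."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        W = (X - X.mean(0)) / X.std(0, ddof=1)
        n, p = W.shape
        num = den = 0.0
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                w = W[:, i] * W[:, j]
                r = w.sum() / (n - 1)
                var = n / (n - 1) ** 3 * ((w - w.mean()) ** 2).sum()
                num += var
                den += r ** 2
        expected = min(1.0, max(0.0, num / den))
        from mwasnet.network import shrinkage_intensity
        assert shrinkage_intensity(X) == pytest.approx(expected, rel=1e-10)


class TestCorToPcor:
    def test_bivariate_partial_equals_correlation(self):
        R = CorrelationMatrix(["a", "b"], np.array([[1.0, 0.45], [0.45, 1.0]]))
        P = cor_to_pcor(R)
        assert P.values[0, 1] == pytest.approx(0.45, abs=1e-12)

    def test_three_by_three_closed_form(self):
        V = np.array([[1.0, 0.6, 0.5], [0.6, 1.0, 0.5], [0.5, 0.5, 1.0]])
        P = cor_to_pcor(CorrelationMatrix(["a", "b", "c"], V))
        assert P.values[0, 1] == pytest.approx((0.6 - 0.25) / 0.75, abs=1e-10)

    def test_identity_maps_to_identity(self):
        P = cor_to_pcor(CorrelationMatrix(["a", "b", "c"], np.eye(3)))
        np.testing.assert_allclose(P.values, np.eye(3), atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 10_000))
    def test_random_3x3_matches_recursive_formula(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 6))
        C = A @ A.T
        d = np.sqrt(np.diag(C))
        R = C / np.outer(d, d)
        np.fill_diagonal(R, 1.0)
        P = cor_to_pcor(CorrelationMatrix(["a", "b", "c"], R))
        for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
            expected = first_order_pcor(R[i, j], R[i, k], R[j, k])
            assert P.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestBuildAssociationNetwork:
    def test_near_unity_threshold_yields_seeds_only(self, choline_fixture):
        table, target, _ = choline_fixture
        net = build_association_network(table, [target], r_min=1 - 1e-9)
        assert net.n_edges == 0
        assert net.n_nodes == 1

    def test_depth2_recovers_secondary_module(self):
        """A secondary module correlated only with primary members is only
        reachable at depth 2."""
        rng_seed = 21
        # chain: anchor - primary - secondary, anchor independent of secondary
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.6   # anchor - primary
        R[1, 2] = R[2, 1] = 0.6   # primary - secondary
        t = _gaussian_table(R, 100, seed=rng_seed)
        seed_q = TargetQuery(mz=float(t.mz[0]), name="seed")
        net1 = build_association_network(t, [seed_q], r_min=0.3, depth_max=1,
                                         corr="pearson")
        net2 = build_association_network(t, [seed_q], r_min=0.3, depth_max=2,
                                         corr="pearson")
        ids = t.feature_ids
        assert ids[1] in net1.graph and ids[2] not in net1.graph
        assert ids[2] in net2.graph
        assert net2.graph.nodes[ids[2]]["depth"] == 2

    def test_unknown_seed_raises(self, choline_fixture):
        table, _, _ = choline_fixture
        with pytest.raises(ValueError, match="seed"):
            build_association_network(table, [TargetQuery(mz=777.7777)])

    def test_invalid_depth_rejected(self, choline_fixture):
        table, target, _ = choline_fixture
        with pytest.raises(ValueError, match="depth"):
            build_association_network(table, [target], depth_max=3)

    def test_node_cap_enforced(self):
        cfg = SimConfig(n_samples=50, n_null_features=20,
                        modules=[ModuleSpec(size=30, r_anchor=0.9, r_within=0.85)],
                        seed=9)
        table, _ = simulate_feature_table(cfg)
        q = TargetQuery(mz=cfg.anchor_mz, rt=cfg.anchor_rt)
        with pytest.raises(RuntimeError, match="cap"):
            build_association_network(table, [q], r_min=0.3, node_cap=5)

    def test_partial_mode_weights_are_partial_correlations(self):
        # chain X1 - X2 - X3: full correlations all strong, but the
        # X1-X3 partial correlation given X2 nearly vanishes
        r = 0.8
        R = np.array([[1, r, r * r], [r, 1, r], [r * r, r, 1]], dtype=float)
        t = _gaussian_table(R, 400, seed=13)
        seed_q = TargetQuery(mz=float(t.mz[1]), name="mid")
        full = build_association_network(t, [seed_q], r_min=0.3, corr="pearson",
                                         method="full")
        part = build_association_network(t, [seed_q], r_min=0.3, corr="pearson",
                                         method="partial")
        ids = t.feature_ids
        assert full.graph.has_edge(ids[0], ids[1])
        assert full.graph.has_edge(ids[1], ids[2])
        # direct chain links survive conditioning, the induced one does not
        assert part.graph.has_edge(ids[0], ids[1])
        assert part.graph.has_edge(ids[1], ids[2])
        assert not part.graph.has_edge(ids[0], ids[2])

    def test_edge_attributes_satisfy_thresholds(self, choline_fixture):
        table, target, _ = choline_fixture
        net = build_association_network(table, [target], r_min=0.3, q_max=0.05)
        for _, _, d in net.graph.edges(data=True):
            assert abs(d["r"]) > 0.3
            assert d["q"] < 0.05


class TestStringencySweep:
    def test_edge_nestedness_on_fixture(self, choline_fixture):
        table, target, _ = choline_fixture
        nets = stringency_sweep(table, [target], thresholds=[0.3, 0.5, 0.7])
        e3, e5, e7 = (n.edge_set() for n in nets)
        assert e7 <= e5 <= e3
        assert len(e3) > len(e5) > len(e7) or len(e3) >= len(e5) >= len(e7)

    def test_edge_counts_strictly_decrease_on_planted_fixture(self):
        cfg = SimConfig(
            n_samples=60, n_null_features=100,
            modules=[ModuleSpec(size=6, r_anchor=0.85, r_within=0.75),
                     ModuleSpec(size=6, r_anchor=0.45)],
            seed=3,
        )
        table, _ = simulate_feature_table(cfg)
        q = TargetQuery(mz=cfg.anchor_mz, rt=cfg.anchor_rt)
        nets = stringency_sweep(table, [q], thresholds=[0.3, 0.5, 0.7])
        counts = [n.n_edges for n in nets]
        assert counts[0] > counts[1] > counts[2]

    def test_single_threshold_equals_plain_build(self, choline_fixture):
        table, target, _ = choline_fixture
        (net,) = stringency_sweep(table, [target], thresholds=[0.4])
        direct = build_association_network(table, [target], r_min=0.4)
        assert net.edge_set() == direct.edge_set()
        assert set(net.graph.nodes) == set(direct.graph.nodes)

    def test_empty_threshold_list_rejected(self, choline_fixture):
        table, target, _ = choline_fixture
        with pytest.raises(ValueError):
            stringency_sweep(table, [target], thresholds=[])

    def test_non_increasing_thresholds_rejected(self, choline_fixture):
        table, target, _ = choline_fixture
        with pytest.raises(ValueError):
            stringency_sweep(table, [target], thresholds=[0.5, 0.3])


class TestPatternSimilarity:
    def _corr(self, ids, V):
        return CorrelationMatrix(list(ids), V)

    def test_identical_matrices_select_everything(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(10, 30))
        C = np.corrcoef(A)
        ids = [f"f{i}" for i in range(10)]
        m = self._corr(ids, C)
        assert pattern_similarity(m, m) == ids

    def test_null_rows_selected_at_about_half_alpha(self):
        # rows of B independent of A -> selection rate ~ alpha/2 (positivity)
        rng = np.random.default_rng(9)
        k, reps, hits, total = 60, 30, 0, 0
        for _ in range(reps):
            A = np.corrcoef(rng.normal(size=(k, 2 * k)))
            B = np.corrcoef(rng.normal(size=(k, 2 * k)))
            ids = [f"f{i}" for i in range(k)]
            hits += len(pattern_similarity(self._corr(ids, A), self._corr(ids, B)))
            total += k
        rate = hits / total
        assert 0.005 < rate < 0.06  # around alpha/2 = 0.025

    def test_two_features_rejected(self):
        m = self._corr(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            pattern_similarity(m, m)

    def test_mismatched_ids_rejected(self):
        A = self._corr(["a", "b", "c"], np.eye(3))
        B = self._corr(["a", "b", "d"], np.eye(3))
        with pytest.raises(ValueError):
            pattern_similarity(A, B)
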
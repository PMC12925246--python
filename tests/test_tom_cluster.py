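"""Topological overlap, hierarchical clustering and the dynamic hybrid cut."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modmix.ggm import PartialCorrelationMatrix
from modmix.tom_cluster import (
    Adjacency,
    CutConfig,
    adjacency_from_partial_corr,
    compute_tom,
    correlation_adjacency,
    cutree_hybrid,
    hierarchical_cluster,
    lambda_grid_scan,
    modules_from_adjacency,
    modules_from_matrix,
    tom_dissimilarity,
)
from modmix.preprocess import standardize
from modmix.synthetic import SimConfig, generate_multiomics

from conftest import make_matrix
from oracles import tom_bruteforce


def _random_adjacency(n, rng):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return a


def _ids(n):
    return [f"f{i}" for i in range(n)]


class TestAdjacency:
    def test_absolute_value(self):
        rho = PartialCorrelationMatrix(_ids(2), np.array([[0.0, -0.4], [-0.4, 0.0]]))
        assert adjacency_from_partial_corr(rho).a[0, 1] == pytest.approx(0.4)

    def test_zero_rho_zero_adjacency(self):
        rho = PartialCorrelationMatrix(_ids(3), np.zeros((3, 3)))
        assert adjacency_from_partial_corr(rho).a.sum() == 0.0

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(-0.5, 0.5, (6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0.0)
        a0 = adjacency_from_partial_corr(PartialCorrelationMatrix(_ids(6), r)).a
        for _ in range(5):
            signs = np.where(rng.random(6) < 0.5, -1.0, 1.0)
            rf = r * np.outer(signs, signs)
            af = adjacency_from_partial_corr(PartialCorrelationMatrix(_ids(6), rf)).a
            np.testing.assert_allclose(af, a0, atol=1e-14)


class TestComputeTOM:
    def test_zero_adjacency_gives_identity(self):
        tom = compute_tom(Adjacency(_ids(4), np.zeros((4, 4))))
        np.testing.assert_array_equal(tom.t, np.eye(4))

    def test_triangle_hand_computation(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = compute_tom(Adjacency(_ids(3), a))
        off = tom.t[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.5, atol=1e-14)

    def test_complete_graph_saturates(self):
        a = np.ones((5, 5)) - np.eye(5)
        tom = compute_tom(Adjacency(_ids(5), a))
        np.testing.assert_allclose(tom.t, np.ones((5, 5)), atol=1e-12)

    def test_single_feature(self):
        tom = compute_tom(Adjacency(["f0"], np.zeros((1, 1))))
        np.testing.assert_array_equal(tom.t, [[1.0]])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = _random_adjacency(15, rng)
            t = compute_tom(Adjacency(_ids(15), a)).t
            np.testing.assert_allclose(t, tom_bruteforce(a), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_entries_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = compute_tom(Adjacency(_ids(n), _random_adjacency(n, rng))).t
        assert t.min() >= 0.0
        assert t.max() <= 1.0 + 1e-12


class TestHierarchicalCluster:
    def test_identical_features_merge_at_zero(self):
        d = np.array([[0.0, 0.0], [0.0, 0.0]])
        dend = hierarchical_cluster(d, _ids(2))
        assert dend.linkage[0, 2] == 0.0

    def test_two_pairs_merge_first(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.2
        z = hierarchical_cluster(d, _ids(4)).linkage
        assert set(z[0, :2].astype(int)) == {0, 1}
        assert set(z[1, :2].astype(int)) == {2, 3}

    def test_heights_monotone(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            d = _random_adjacency(12, rng)
            z = hierarchical_cluster(d, _ids(12)).linkage
            assert np.all(np.diff(z[:, 2]) >= -1e-12)

    def test_single_feature_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(np.zeros((1, 1)), ["f0"])

    def test_newick_export_parses(self):
        d = np.array([[0.0, 0.2, 0.9], [0.2, 0.0, 0.8], [0.9, 0.8, 0.0]])
        nwk = hierarchical_cluster(d, ["a", "b", "c"]).to_newick()
        assert nwk.endswith(";")
        assert {"a", "b", "c"} <= set(nwk.replace("(", " ").replace(")", " ")
                                      .replace(",", " ").replace(":", " ").split())


def _planted_blocks(n_blocks=2, size=20, high=0.8, low=0.001, rng=None):
    # near-zero cross-block adjacency: TOM chaining amplifies even modest
    # background weights, so "separated" means low << high/size
    n = n_blocks * size
    a = np.full((n, n), low)
    for b in range(n_blocks):
        sl = slice(b * size, (b + 1) * size)
        a[sl, sl] = high
    np.fill_diagonal(a, 0.0)
    if rng is not None:
        noise = rng.uniform(-0.0005, 0.0005, (n, n))
        a += (noise + noise.T) / 2
        np.clip(a, 0.0, 1.0, out=a)
        np.fill_diagonal(a, 0.0)
    return a


class TestCutreeHybrid:
    def test_recovers_two_planted_blocks(self):
        rng = np.random.default_rng(3)
        a = _planted_blocks(rng=rng)
        assign, _, _ = modules_from_adjacency(Adjacency(_ids(40), a))
        assert assign.n_modules == 2
        assert sorted(assign.module_sizes.values()) == [20, 20]
        first_block = assign.labels[:20]
        assert len(set(first_block)) == 1

    def test_min_size_larger_than_n_all_unassigned(self):
        rng = np.random.default_rng(4)
        d = _random_adjacency(12, rng)
        dend = hierarchical_cluster(d, _ids(12))
        assign = cutree_hybrid(dend, d, CutConfig(min_module_size=13))
        assert (assign.labels == 0).all()

    def test_labels_ordered_by_size(self, standard_run):
        for assign in standard_run["assignments"].values():
            sizes = [assign.module_sizes[l] for l in sorted(assign.module_sizes)]
            assert sizes == sorted(sizes, reverse=True)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        a = _planted_blocks(rng=rng)
        assign, _, _ = modules_from_adjacency(Adjacency(_ids(40), a))
        perm = rng.permutation(40)
        ap = a[np.ix_(perm, perm)]
        assign_p, _, _ = modules_from_adjacency(
            Adjacency([f"f{i}" for i in perm], ap))
        # same partition up to label renumbering
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(assign.labels[perm], assign_p.labels) == 1.0


class TestCorrelationAdjacencyMode:
    def test_identical_features_power_one(self):
        x = np.vstack([np.linspace(0, 1, 10)] * 2)
        m = standardize(make_matrix(x + np.random.default_rng(6).normal(0, 1e-9, x.shape)))
        a = correlation_adjacency(m, 1).a
        assert a[0, 1] == pytest.approx(1.0, abs=1e-6)

    def test_power_shrinks_subunit_entries(self):
        rng = np.random.default_rng(7)
        m = standardize(make_matrix(rng.standard_normal((5, 30))))
        a1 = correlation_adjacency(m, 1).a
        a3 = correlation_adjacency(m, 3).a
        off = ~np.eye(5, dtype=bool)
        assert (a3[off] <= a1[off] + 1e-15).all()


@pytest.fixture(scope="module")
def small_matrix():
    mats, _, _ = generate_multiomics(SimConfig(
        n_samples=60, n_modules=3, module_size=12, background_features=6,
        n_cross_links=0, n_datasets=1, seed=5))
    return standardize(mats[0])


class TestLambdaGridScan:
    def test_full_shrinkage_row(self, small_matrix):
        table = lambda_grid_scan(small_matrix, [0.999])
        assert table.loc[0, "n_modules"] == 0
        assert table.loc[0, "frac_unassigned"] == 1.0

    def test_single_lambda_matches_direct_run(self, small_matrix):
        table = lambda_grid_scan(small_matrix, [0.25])
        assign, _, _, _ = modules_from_matrix(small_matrix)
        assert table.loc[0, "n_modules"] == assign.n_modules

    def test_module_count_weakly_decreasing_at_high_lambda(self, small_matrix):
        table = lambda_grid_scan(small_matrix, [0.3, 0.5, 0.8])
        counts = table["n_modules"].tolist()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
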
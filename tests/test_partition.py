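import itertools

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from metapile.cell_graph import WeightedCellGraph
from metapile.config import PartitionParams
from metapile.data_io import CellSizes
from metapile.partition import (
    OUTLIER,
    compact_labels,
    compute_score,
    enforce_connectivity,
    enforce_max_size,
    enforce_min_size,
    optimize_partition,
    partition_pile,
    seed_partition,
)

from helpers import dense_matrix


def graph_from_dense(W) -> WeightedCellGraph:
    W = np.asarray(W, dtype=np.float64)
    return WeightedCellGraph(out_csr=sp.csr_matrix(W), K=W.shape[0] - 1,
                             isolated=np.empty(0, np.int64))


def complete_graph(n, weight=1.0):
    W = np.full((n, n), weight)
    np.fill_diagonal(W, 0.0)
    return W


def two_cliques(n1, n2, cross=0.0):
    n = n1 + n2
    W = np.zeros((n, n))
    W[:n1, :n1] = 1.0
    W[n1:, n1:] = 1.0
    if cross:
        W[0, n1] = W[n1, 0] = cross
    np.fill_diagonal(W, 0.0)
    return W


def brute_force_score(W, mc, floor=-10.0):
    """Direct-sum oracle for the two-sided stability score."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    sizes = np.bincount(mc, minlength=mc.max() + 1)
    total = 0.0
    for v in range(n):
        punif = sizes[mc[v]] / n
        for vec in (W[v, :], W[:, v]):  # out side, in side
            wtot = vec.sum()
            win = vec[mc == mc[v]].sum()
            if wtot > 0 and win > 0:
                total += np.log((win / wtot) / punif)
            else:
                total += floor
    return total / (2 * n)


def all_partitions(n):
    """Every partition of range(n) as a label array (restricted growth)."""
    labels = np.zeros(n, dtype=np.int64)

    def rec(i, mx):
        if i == n:
            yield labels.copy()
            return
        for v in range(mx + 1):
            labels[i] = v
            yield from rec(i + 1, max(mx, v + 1))

    yield from rec(0, 0)


class TestComputeScore:
    def test_single_metacell_scores_zero(self):
        g = graph_from_dense(complete_graph(6))
        terms = compute_score(g, np.zeros(6, dtype=int))
        assert terms.score == pytest.approx(0.0)
        assert np.allclose(terms.pstable_out, 1.0)
        assert np.allclose(terms.punif, 1.0)

    def test_two_components_score_ln2(self):
        W = two_cliques(6, 6)
        g = graph_from_dense(W)
        mc = np.array([0] * 6 + [1] * 6)
        terms = compute_score(g, mc)
        assert terms.score == pytest.approx(np.log(2))
        assert np.allclose(terms.pstable_in, 1.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for n in (5, 6, 7):
            W = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
            np.fill_diagonal(W, 0.0)
            g = graph_from_dense(W)
            for mc in all_partitions(n):
                assert compute_score(g, mc).score == pytest.approx(
                    brute_force_score(W, mc), abs=1e-12
                )

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        W = rng.random((10, 10))
        np.fill_diagonal(W, 0.0)
        g = graph_from_dense(W)
        mc = rng.integers(0, 3, size=10)
        relabeled = np.array([2, 0, 1])[mc]
        assert compute_score(g, mc).score == pytest.approx(
            compute_score(g, relabeled).score
        )

    def test_outliers_excluded_from_scoring(self):
        W = two_cliques(6, 6)
        g = graph_from_dense(W)
        mc = np.array([0] * 6 + [OUTLIER] * 6)
        terms = compute_score(g, mc)
        assert terms.score == pytest.approx(0.0)  # one metacell over V=6


class TestSeedPartition:
    def test_single_seed_covers_all(self):
        g = graph_from_dense(complete_graph(8))
        mc = seed_partition(g, 1, np.random.default_rng(0))
        assert (mc == 0).all()

    def test_p_clamped_to_n(self):
        g = graph_from_dense(complete_graph(4))
        mc = seed_partition(g, 99, np.random.default_rng(0))
        assert mc.min() >= 0 and len(np.unique(mc)) <= 4

    @pytest.mark.parametrize("seed", range(5))
    def test_disconnected_cliques_get_separate_seeds(self, seed):
        g = graph_from_dense(two_cliques(6, 6))
        mc = seed_partition(g, 2, np.random.default_rng(seed))
        # exclusion sampling makes cross-clique seeding certain
        assert len(np.unique(mc[:6])) == 1
        assert len(np.unique(mc[6:])) == 1
        assert mc[0] != mc[6]

    def test_full_cover(self):
        rng = np.random.default_rng(3)
        W = (rng.random((30, 30)) < 0.2) * rng.random((30, 30))
        np.fill_diagonal(W, 0.0)
        mc = seed_partition(graph_from_dense(W), 4, rng)
        assert (mc >= 0).all()


class TestOptimizePartition:
    def test_optimal_partition_is_fixed_point(self):
        g = graph_from_dense(two_cliques(6, 6))
        mc0 = np.array([0] * 6 + [1] * 6)
        mc = optimize_partition(g, mc0, np.random.default_rng(0))
        assert (mc == mc0).all() or (mc == 1 - mc0).all()

    def test_score_never_decreases(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            W = (rng.random((15, 15)) < 0.4) * rng.random((15, 15))
            np.fill_diagonal(W, 0.0)
            g = graph_from_dense(W)
            mc0 = rng.integers(0, 3, size=15)
            mc = optimize_partition(g, mc0, rng)
            assert compute_score(g, mc).score >= compute_score(g, mc0).score - 1e-9

    def test_adversarial_start_reaches_enumerated_optimum(self):
        # 12 nodes, two planted clusters, worst-case interleaved start
        rng = np.random.default_rng(11)
        W = two_cliques(6, 6, cross=0.0)
        W += (rng.random((12, 12)) < 0.3) * 0.05  # weak noise edges
        np.fill_diagonal(W, 0.0)
        g = graph_from_dense(W)
        best = max(
            compute_score(g, np.array(mc)).score
            for mc in itertools.product([0, 1], repeat=12)
            if 0 < sum(mc) < 12
        )
        mc0 = np.arange(12) % 2  # interleaved adversarial start
        mc = optimize_partition(g, mc0, np.random.default_rng(0))
        assert compute_score(g, mc).score >= best - 1e-9

    def test_rejects_outliers_in_input(self):
        g = graph_from_dense(complete_graph(5))
        with pytest.raises(ValueError):
            optimize_partition(g, np.array([0, 0, 1, 1, OUTLIER]),
                               np.random.default_rng(0))


def _sizes(u, target):
    return CellSizes.from_totals(np.asarray(u, float), target,
                                 min_cells_per_metacell=2)


class TestSizeControl:
    def test_max_size_noop_within_bounds(self):
        g = graph_from_dense(two_cliques(6, 6))
        mc = np.array([0] * 6 + [1] * 6)
        sizes = CellSizes(u=np.full(12, 100.0), u_capped=np.full(12, 100.0),
                          U_targ=600, U_low=300.0, U_high=1200.0)
        out, n = enforce_max_size(g, mc, sizes, np.random.default_rng(0))
        assert n == 0 and (out == mc).all()

    def test_max_size_dissolves_and_preserves_cover(self):
        g = graph_from_dense(two_cliques(8, 8))
        mc = np.zeros(16, dtype=int)  # one huge metacell
        sizes = CellSizes(u=np.full(16, 100.0), u_capped=np.full(16, 100.0),
                          U_targ=800, U_low=400.0, U_high=1600.0)
        out, n = enforce_max_size(g, mc, sizes, np.random.default_rng(0))
        assert n == 1
        assert (out >= 0).all()
        totals = np.bincount(out, weights=sizes.u_capped)
        assert (totals[totals > 0] < sizes.U_high).all()

    def test_connectivity_keeps_clique(self):
        g = graph_from_dense(complete_graph(10))
        mc = np.zeros(10, dtype=int)
        sizes = CellSizes(u=np.full(10, 10.0), u_capped=np.full(10, 10.0),
                          U_targ=100, U_low=50.0, U_high=200.0)
        out, changed = enforce_connectivity(g, mc, np.random.default_rng(0), sizes)
        assert not changed and (out == 0).all()

    def test_connectivity_splits_dumbbell(self):
        # two 10-cliques joined by one epsilon edge, forced into one metacell
        W = two_cliques(10, 10, cross=1e-4)
        g = graph_from_dense(W)
        mc = np.zeros(20, dtype=int)
        sizes = CellSizes(u=np.full(20, 10.0), u_capped=np.full(20, 10.0),
                          U_targ=100, U_low=50.0, U_high=10_000.0)
        out, changed = enforce_connectivity(g, mc, np.random.default_rng(0), sizes)
        assert changed
        assert len(np.unique(out[out >= 0])) >= 2  # dissolved and re-seeded apart

    def test_connectivity_disassociates_small_weak_side(self):
        # 20-clique plus 3 cells attached by feeble edges
        n = 23
        W = np.zeros((n, n))
        W[:20, :20] = 1.0
        for extra in (20, 21, 22):
            W[extra, extra - 20] = W[extra - 20, extra] = 1e-5
        np.fill_diagonal(W, 0.0)
        g = graph_from_dense(W)
        mc = np.zeros(n, dtype=int)
        sizes = CellSizes(u=np.full(n, 10.0), u_capped=np.full(n, 10.0),
                          U_targ=150, U_low=75.0, U_high=10_000.0)
        out, changed = enforce_connectivity(g, mc, np.random.default_rng(0), sizes)
        assert changed
        assert (out[20:] == OUTLIER).all()
        assert (out[:20] == out[0]).all() and out[0] >= 0

    def test_min_size_noop_when_compliant(self):
        g = graph_from_dense(two_cliques(12, 12))
        mc = np.array([0] * 12 + [1] * 12)
        counts = sp.csr_matrix(np.ones((24, 5), dtype=np.int64))
        sizes = CellSizes(u=np.full(24, 100.0), u_capped=np.full(24, 100.0),
                          U_targ=1200, U_low=600.0, U_high=2400.0)
        out, warnings = enforce_min_size(g, mc, sizes, counts,
                                         np.random.default_rng(0))
        assert (out == mc).all() and not warnings

    def test_small_metacell_dissolved_on_cell_count(self):
        # 10-cell metacell violates the 12-cell floor regardless of UMIs
        g = graph_from_dense(complete_graph(40))
        mc = np.array([0] * 10 + [1] * 30)
        counts = sp.csr_matrix(np.ones((40, 5), dtype=np.int64))
        sizes = CellSizes(u=np.full(40, 1000.0), u_capped=np.full(40, 1000.0),
                          U_targ=2000, U_low=1000.0, U_high=1_000_000.0)
        out, _ = enforce_min_size(g, mc, sizes, counts, np.random.default_rng(0))
        labels, counts_per = np.unique(out[out >= 0], return_counts=True)
        assert (counts_per >= 12).all()

    def test_marker_metacell_kept_at_half_floor(self):
        # metacell at 0.6*U_low carrying an 8-fold marker gene survives
        g = graph_from_dense(two_cliques(12, 12))
        mc = np.array([0] * 12 + [1] * 12)
        X = np.ones((24, 6), dtype=np.int64) * 10
        X[:12, 0] = 200  # marker gene for metacell 0
        counts = sp.csr_matrix(X)
        u = np.array([50.0] * 12 + [200.0] * 12)  # mc0 total 600 = 0.6*U_low
        sizes = CellSizes(u=u, u_capped=u, U_targ=2000, U_low=1000.0,
                          U_high=1_000_000.0)
        out, _ = enforce_min_size(g, mc, sizes, counts, np.random.default_rng(0))
        assert len(np.unique(out[:12])) == 1
        assert set(out[:12]) != set(out[12:])


class TestPartitionPile:
    def test_planted_states_recovered(self, four_state_matrix):
        from metapile.cell_graph import build_balanced_knn, choose_K, select_features
        from metapile.data_io import choose_downsample_target, downsample_cells

        m, truth = four_state_matrix
        u = m.cell_totals().astype(float)
        target = 30_000
        ds = downsample_cells(m, choose_downsample_target(u, target), 0)
        sel = select_features(ds)
        g = build_balanced_knn(ds, sel.feature_genes, choose_K(u, target))
        res = partition_pile(g, u, ds.X, target, np.random.default_rng(0))
        mc = res.mc
        assigned = mc >= 0
        assert assigned.mean() > 0.9  # only weakly attached cells disassociate
        purities = []
        sizes = CellSizes.from_totals(u, target)
        for k in np.unique(mc[assigned]):
            lab = truth.state_labels[mc == k]
            _, c = np.unique(lab, return_counts=True)
            purities.append(c.max() / len(lab))
        assert np.mean(np.asarray(purities) >= 0.9) >= 0.95
        totals = np.bincount(mc[assigned], weights=sizes.u_capped[assigned])
        members = np.bincount(mc[assigned])
        live = members > 0
        assert (totals[live] < sizes.U_high).all()
        assert (members[live] >= 12).all()

    def test_tiny_graph_degenerates_gracefully(self):
        g = graph_from_dense(complete_graph(5))
        res = partition_pile(g, np.full(5, 100.0), sp.csr_matrix(np.ones((5, 3))),
                             1000, np.random.default_rng(0))
        assert (res.mc == 0).all()
        assert res.warnings

    def test_forced_coverage_leaves_no_outliers(self):
        W = two_cliques(15, 15, cross=1e-4)
        g = graph_from_dense(W)
        counts = sp.csr_matrix(np.ones((30, 4), dtype=np.int64))
        res = partition_pile(g, np.full(30, 100.0), counts, 1500,
                             np.random.default_rng(0), force_coverage=True)
        assert (res.mc >= 0).all()


class TestCompactLabels:
    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(-1, 20), min_size=1, max_size=40))
    def test_dense_and_order_preserving(self, labels):
        mc = np.asarray(labels, dtype=np.int64)
        out = compact_labels(mc)
        assert ((out == -1) == (mc == -1)).all()
        valid = out[out >= 0]
        if valid.size:
            assert set(valid) == set(range(valid.max() + 1))
        # equal labels stay equal, distinct stay distinct
        for a in range(len(mc)):
            for b in range(len(mc)):
                if mc[a] >= 0 and mc[b] >= 0:
                    assert (mc[a] == mc[b]) == (out[a] == out[b])
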
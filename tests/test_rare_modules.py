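import numpy as np
import pytest
import scipy.sparse as sp

from metapile.config import RareModuleParams
from metapile.data_io import UMIMatrix
from metapile.rare_modules import (
    RareGeneModule,
    candidate_modules,
    detect_rare_modules,
    expand_module,
    find_rare_genes,
    modules_report,
    second_order_correlation,
)
from metapile.synthetic import generate_states, plant_rare_type

from helpers import dense_matrix


def _matrix_with_gene_pattern(n_cells, columns) -> UMIMatrix:
    """cells x len(columns) matrix; each column is a dict cell -> count."""
    X = sp.lil_matrix((n_cells, len(columns)), dtype=np.int64)
    for j, col in enumerate(columns):
        for cell, count in col.items():
            X[cell, j] = count
    cells = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    genes = np.array([f"g{j}" for j in range(len(columns))], dtype=object)
    return UMIMatrix(X.tocsr(), cells, genes)


class TestFindRareGenes:
    def test_thresholds(self):
        n = 10_000
        m = _matrix_with_gene_pattern(n, [
            {i: 8 for i in range(5)},                   # 5 cells, max 8 -> rare
            {i: 3 for i in range(200)},                 # 2% of cells -> not rare
            {i: 5 for i in range(3)},                   # max 5 < 7 -> not rare
            {i: 1 for i in range(n)},                   # ubiquitous -> not rare
        ])
        rare = find_rare_genes(m, RareModuleParams())
        assert rare.tolist() == [0]

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            find_rare_genes(
                UMIMatrix(sp.csr_matrix((0, 0), dtype=np.int64),
                          np.empty(0, object), np.empty(0, object)),
                RareModuleParams(),
            )


class TestSecondOrderCorrelation:
    def test_identical_vectors_fully_correlated(self):
        v = np.array([1.0, 4.0, 0.0, 3.0, 2.0, 8.0])
        expr = np.vstack([v, v, -v + 5, np.random.default_rng(0).random(6)])
        r2 = second_order_correlation(expr)
        assert r2.shape == (4, 4)
        assert np.allclose(np.diag(r2), 1.0)
        assert np.allclose(r2, r2.T)
        assert r2[0, 1] == pytest.approx(1.0)

    def test_zero_variance_rows_give_zero(self):
        expr = np.vstack([np.ones(5), np.arange(5.0), np.arange(5.0)[::-1]])
        r2 = second_order_correlation(expr)
        assert np.isfinite(r2).all()

    def test_requires_two_genes(self):
        with pytest.raises(ValueError):
            second_order_correlation(np.ones((1, 10)))


def _block_r2(blocks, n, high=0.9, low=0.0):
    """Symmetric r2 matrix with given index blocks at ``high`` correlation."""
    r2 = np.full((n, n), low)
    for block in blocks:
        for i in block:
            for j in block:
                r2[i, j] = high
    np.fill_diagonal(r2, 1.0)
    return r2


class TestCandidateModules:
    def test_identity_matrix_yields_nothing(self):
        assert candidate_modules(np.eye(8), RareModuleParams()) == []

    def test_single_block_recovered_exactly(self):
        # enough uncorrelated background that no ancestor of the block
        # keeps a qualifying mean r2
        block = [1, 2, 4, 6, 7]
        r2 = _block_r2([block], 30)
        mods = candidate_modules(r2, RareModuleParams())
        assert len(mods) == 1
        assert mods[0].tolist() == sorted(block)

    def test_two_disjoint_blocks(self):
        r2 = _block_r2([[0, 1, 2, 3], [10, 11, 12, 13, 14]], 30)
        mods = candidate_modules(r2, RareModuleParams())
        assert len(mods) == 2
        sets = [set(mod.tolist()) for mod in mods]
        assert {0, 1, 2, 3} in sets and {10, 11, 12, 13, 14} in sets
        assert sets[0] & sets[1] == set()

    def test_returned_subtrees_qualify_and_are_maximal(self):
        # every returned module satisfies the size/mean-r2 rule and is not
        # nested in another returned module
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.02, size=(15, 15))
        r2 = np.clip(_block_r2([[0, 1, 2, 3, 4, 5]], 15, high=0.6) + (noise + noise.T) / 2, -1, 1)
        np.fill_diagonal(r2, 1.0)
        params = RareModuleParams()
        mods = candidate_modules(r2, params)
        assert mods
        for mod in mods:
            sub = r2[np.ix_(mod, mod)]
            k = len(mod)
            assert k >= params.min_module_genes
            assert (sub.sum() - np.trace(sub)) / (k * (k - 1)) >= params.min_mean_r2
        for a in mods:
            for b in mods:
                if a is not b:
                    assert not set(a).issubset(set(b))


class TestExpandModule:
    def test_too_few_cells_discarded(self):
        # module expressed by only 8 cells -> below the 12-cell floor
        m = _matrix_with_gene_pattern(1000, [
            {i: 5 for i in range(8)},
            {i: 5 for i in range(8)},
            {i: 2 for i in range(1000)},
        ])
        mod = expand_module(np.array([0, 1]), m, RareModuleParams(), 500)
        assert mod.discarded and mod.discard_reason == "too_few"

    def test_too_common_discarded(self):
        m = _matrix_with_gene_pattern(1000, [
            {i: 5 for i in range(500)},
            {i: 5 for i in range(500)},
            {i: 2 for i in range(1000)},
        ])
        mod = expand_module(np.array([0, 1]), m, RareModuleParams(), 100)
        assert mod.discarded and mod.discard_reason == "too_common"

    def test_enriched_marker_joins_expansion(self):
        # 15 module cells; gene 2 is expressed only there (huge enrichment)
        # and adds no new cells, so it must join the expanded set
        m = _matrix_with_gene_pattern(60_000, [
            {i: 4 for i in range(15)},
            {i: 4 for i in range(15)},
            {i: 6 for i in range(15)},
            {i: 1 for i in range(60_000)},
        ])
        mod = expand_module(np.array([0, 1]), m, RareModuleParams(), 500)
        assert not mod.discarded
        assert 2 in mod.expanded_genes
        assert 3 not in mod.expanded_genes
        assert mod.cells.size == 15

    def test_seed_subset_invariant(self):
        mod = RareGeneModule(np.array([1, 2]), np.array([1, 2, 5]))
        assert set(mod.seed_genes).issubset(set(mod.expanded_genes))
        with pytest.raises(ValueError):
            RareGeneModule(np.array([1, 9]), np.array([1, 2]))


class TestDetectRareModules:
    def test_no_rare_genes_yields_empty(self, two_state_matrix):
        m, _ = two_state_matrix
        mods, assignment = detect_rare_modules(m, RareModuleParams(), pile_size=200)
        # a small clean 2-state matrix has no coherent rare module
        assert all(not mod.discarded for mod in mods)
        assert (assignment >= -1).all()

    def test_planted_module_recovered_small_scale(self):
        m, truth = generate_states(2, 1000, 30_000, seed=21)
        m, truth = plant_rare_type(m, truth, 5e-4, seed=21)  # 15 cells
        mods, assignment = detect_rare_modules(m, RareModuleParams(), pile_size=3000)
        planted = set(truth.rare_cells)
        best = 0.0
        for mod in mods:
            got = set(mod.cells.tolist())
            best = max(best, len(got & planted) / len(planted))
        assert best >= 0.9

    def test_two_disjoint_planted_modules(self):
        m, truth = generate_states(2, 1000, 30_000, seed=22)
        m, truth = plant_rare_type(m, truth, 5e-4, seed=22)
        m, truth = plant_rare_type(m, truth, 5e-4, seed=23)
        mods, assignment = detect_rare_modules(m, RareModuleParams(), pile_size=3000)
        assert len(mods) == 2
        cells = [set(mod.cells.tolist()) for mod in mods]
        assert cells[0] & cells[1] == set()
        # module size guard holds for every kept module
        for mod in mods:
            assert 12 <= mod.cells.size <= np.ceil(48 * m.n_cells / 3000)

    def test_assignment_matches_modules(self):
        m, truth = generate_states(2, 1000, 20_000, seed=24)
        m, truth = plant_rare_type(m, truth, 1e-3, seed=24)
        mods, assignment = detect_rare_modules(m, RareModuleParams(), pile_size=2000)
        for idx, mod in enumerate(mods):
            assert (np.flatnonzero(assignment == idx) == mod.cells).all()

    def test_report_frame(self):
        m, truth = generate_states(2, 1000, 20_000, seed=25)
        m, truth = plant_rare_type(m, truth, 1e-3, seed=25)
        mods, _ = detect_rare_modules(m, RareModuleParams(), pile_size=2000)
        frame = modules_report(mods, m.gene_ids)
        assert list(frame.columns) == ["module_id", "seed_genes", "expanded_genes",
                                       "n_cells", "status"]
        assert len(frame) == len(mods)
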
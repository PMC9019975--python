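import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from metapile.data_io import (
    RECIPES,
    CellSizes,
    FilterRecipe,
    FormatError,
    InputError,
    UMIMatrix,
    apply_filter_recipe,
    choose_downsample_target,
    downsample_cells,
    load_umi_matrix,
    save_umi_matrix,
)

from helpers import dense_matrix


class TestUMIMatrix:
    def test_rejects_shape_mismatch(self):
        with pytest.raises(FormatError):
            UMIMatrix(sp.csr_matrix(np.eye(3)), ["a", "b"], ["x", "y", "z"])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(FormatError, match="duplicate"):
            dense_matrix([[1, 2], [3, 4]]).__class__(
                sp.csr_matrix([[1, 2], [3, 4]]), ["a", "a"], ["x", "y"]
            )

    def test_rejects_fractional_counts(self):
        with pytest.raises(FormatError, match="non-integer"):
            UMIMatrix(sp.csr_matrix([[1.5, 0.0]]), ["a"], ["x", "y"])

    def test_accepts_float_integers(self):
        m = UMIMatrix(sp.csr_matrix([[2.0, 0.0]]), ["a"], ["x", "y"])
        assert np.issubdtype(m.X.dtype, np.integer)

    def test_totals(self):
        m = dense_matrix([[1, 2, 0], [0, 0, 5]])
        assert m.cell_totals().tolist() == [3, 5]
        assert m.gene_totals().tolist() == [1, 2, 5]


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["mtx_dir", "h5"])
    def test_save_load_identity(self, tmp_path, fmt):
        m = dense_matrix([[3, 0, 1, 0], [0, 2, 0, 0], [1, 1, 1, 1]])
        path = tmp_path / ("out" if fmt == "mtx_dir" else "out.h5ad")
        save_umi_matrix(m, path, fmt=fmt)
        back = load_umi_matrix(path, fmt=fmt)
        assert (back.X != m.X).nnz == 0
        assert list(back.cell_ids) == list(m.cell_ids)
        assert list(back.gene_ids) == list(m.gene_ids)

    def test_mtx_is_transposed_on_disk(self, tmp_path):
        # 10x convention stores genes x cells; loading restores cells x genes
        m = dense_matrix([[1, 0, 0], [0, 5, 2]])  # 2 cells x 3 genes
        save_umi_matrix(m, tmp_path / "d", fmt="mtx_dir")
        import scipy.io

        raw = scipy.io.mmread(str(tmp_path / "d" / "matrix.mtx"))
        assert raw.shape == (3, 2)
        back = load_umi_matrix(tmp_path / "d")
        assert back.n_cells == 2 and back.n_genes == 3

    def test_missing_path_is_input_error(self, tmp_path):
        with pytest.raises(InputError):
            load_umi_matrix(tmp_path / "nope")

    def test_empty_matrix_is_error(self, tmp_path):
        d = tmp_path / "d"
        d.mkdir()
        (d / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n0 0 0\n"
        )
        (d / "barcodes.tsv").write_text("")
        (d / "genes.tsv").write_text("")
        with pytest.raises((FormatError, InputError)):
            load_umi_matrix(d)


class TestFilterRecipe:
    def test_low_umi_cell_removed(self):
        m = dense_matrix([[500, 0], [900, 0]])
        kept, report = apply_filter_recipe(m, FilterRecipe(min_cell_umis=800))
        assert kept.n_cells == 1 and report.n_cells_low_umis == 1
        assert report.removed_cell_ids == ["c0"]

    def test_identity_recipe(self, two_state_matrix):
        m, _ = two_state_matrix
        kept, report = apply_filter_recipe(
            m, FilterRecipe(exclude_mitochondrial=False)
        )
        # only all-zero genes may go; no cells
        assert kept.n_cells == m.n_cells
        assert report.n_cells_removed == 0
        assert report.n_genes_removed == report.n_all_zero_genes

    def test_planted_low_depth_cells_removed_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.integers(9, 20, size=(1000, 50))  # totals ~ 700
        low = rng.choice(1000, size=50, replace=False)
        X[low] = 0
        X[low, 0] = 5  # 50 planted low-depth cells
        m = dense_matrix(X)
        kept, report = apply_filter_recipe(
            m, FilterRecipe(min_cell_umis=100, exclude_mitochondrial=False)
        )
        assert report.n_cells_removed == 50
        assert kept.n_cells == 950

    def test_mitochondrial_prefix_case_insensitive(self):
        m = UMIMatrix(sp.csr_matrix([[1, 2, 3, 9]]), np.array(["c"]),
                      np.array(["MT-CO1", "mt-nd1", "MTX1", "ACTB"]))
        kept, report = apply_filter_recipe(m, FilterRecipe(max_excluded_fraction=1.0))
        assert set(report.removed_gene_names) == {"MT-CO1", "mt-nd1"}
        assert kept.n_genes == 2

    def test_excluded_fraction_uses_pre_removal_total(self):
        # cell0: 3 of 10 UMIs in the excluded gene (30%) -> removed at 10% cap
        m = UMIMatrix(sp.csr_matrix([[3, 7], [0, 10]]), np.array(["a", "b"]),
                      np.array(["BAD", "OK"]))
        kept, report = apply_filter_recipe(
            m, FilterRecipe(excluded_gene_names={"BAD"}, max_excluded_fraction=0.1,
                            exclude_mitochondrial=False)
        )
        assert report.n_cells_excluded_fraction == 1
        assert list(kept.cell_ids) == ["b"]

    def test_idempotent(self, two_state_matrix):
        m, _ = two_state_matrix
        recipe = FilterRecipe(min_cell_umis=600, max_cell_umis=6000,
                              max_excluded_fraction=0.5)
        once, _ = apply_filter_recipe(m, recipe)
        twice, report = apply_filter_recipe(once, recipe)
        assert twice.n_cells == once.n_cells and twice.n_genes == once.n_genes
        assert report.n_cells_removed == 0

    def test_all_cells_removed_is_error(self):
        m = dense_matrix([[1, 0], [2, 0]])
        with pytest.raises(InputError, match="every cell"):
            apply_filter_recipe(m, FilterRecipe(min_cell_umis=100))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            FilterRecipe(min_cell_umis=10, max_cell_umis=5)
        with pytest.raises(ValueError):
            FilterRecipe(max_excluded_fraction=1.5)

    def test_presets_exist_with_published_bounds(self):
        assert RECIPES["pbmc"].min_cell_umis == 800
        assert RECIPES["pbmc"].max_cell_umis == 8000
        assert RECIPES["pbmc"].max_excluded_fraction == 0.10
        assert "TMSB4X" in RECIPES["pbmc"].excluded_gene_names
        assert RECIPES["hca_bm"].max_cell_umis == 25_000
        assert RECIPES["moca"].min_cell_umis == 300

    def test_recipe_yaml_round_trip(self, tmp_path):
        recipe = RECIPES["pbmc"]
        recipe.to_yaml(tmp_path / "r.yaml")
        back = FilterRecipe.from_yaml(tmp_path / "r.yaml")
        assert back.excluded_gene_names == recipe.excluded_gene_names
        assert back.min_cell_umis == recipe.min_cell_umis


class TestDownsample:
    def test_cell_at_target_unchanged(self):
        m = dense_matrix([[5, 5], [2, 0]])
        out = downsample_cells(m, 10, seed=0)
        assert out.X[0].toarray().tolist() == [[5, 5]]
        assert out.X[1].toarray().tolist() == [[2, 0]]

    def test_exact_target_and_monotone(self):
        rng = np.random.default_rng(3)
        m = dense_matrix(rng.integers(0, 40, size=(30, 60)))
        out = downsample_cells(m, 300, seed=1)
        totals = out.cell_totals()
        original = m.cell_totals()
        assert (totals[original > 300] == 300).all()
        assert (totals[original <= 300] == original[original <= 300]).all()
        assert (out.X.toarray() <= m.X.toarray()).all()

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        m = dense_matrix(rng.integers(0, 30, size=(10, 40)))
        a = downsample_cells(m, 200, seed=9).X.toarray()
        b = downsample_cells(m, 200, seed=9).X.toarray()
        assert (a == b).all()

    def test_hypergeometric_expectation(self):
        # mean downsampled count over many seeds ~ original * target/total
        m = dense_matrix([[120, 60, 20]])  # total 200
        target = 100
        acc = np.zeros(3)
        n_seeds = 400
        for s in range(n_seeds):
            acc += downsample_cells(m, target, seed=s).X.toarray()[0]
        mean = acc / n_seeds
        expected = np.array([120, 60, 20]) * target / 200
        assert np.allclose(mean, expected, rtol=0.05)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=3, max_size=12),
           st.integers(1, 80), st.integers(0, 2**31 - 1))
    def test_conservation_property(self, counts, target, seed):
        m = dense_matrix(np.asarray(counts)[None, :])
        out = downsample_cells(m, target, seed=seed)
        total = sum(counts)
        assert out.cell_totals()[0] == min(total, target)
        assert (out.X.toarray() <= m.X.toarray()).all()

    def test_target_choice_clipped(self):
        totals = np.array([1000, 2000, 3000, 4000, 100_000])
        t = choose_downsample_target(totals, target_umis=160_000, min_umis=500)
        assert 500 <= t <= 160_000
        assert t == int(np.clip(np.percentile(totals, 5), 500, 160_000))


class TestCellSizes:
    def test_capping_and_bounds(self):
        u = np.array([100, 200, 300, 400, 10_000])
        s = CellSizes.from_totals(u, target_umis=4000)
        assert (s.u_capped == np.minimum(u, 2 * np.median(u))).all()
        assert s.U_low == s.U_targ / 2
        assert s.U_high == 2 * s.U_targ

    def test_target_raised_for_large_cells(self):
        # 160k target over median-100k cells would give <12 cells/metacell
        u = np.full(50, 100_000)
        s = CellSizes.from_totals(u, target_umis=160_000)
        assert s.U_targ == 12 * 100_000
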
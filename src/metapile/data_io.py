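"""UMI matrix container, readers/writers, cleaning recipes, and downsampling.

The central object is :class:`UMIMatrix`: a sparse cells x genes matrix of
non-negative integer UMI counts with unique cell and gene names.  Matrices
can be read from 10x-style Matrix Market directories (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``/``genes.tsv``, optionally gzipped) or
from an HDF5 container in the AnnData on-disk layout, and written back to
either format.

Cleaning is expressed as a :class:`FilterRecipe` (excluded gene names,
mitochondrial exclusion, per-cell UMI bounds, and a cap on the fraction of a
cell's UMIs coming from excluded genes).  Recipes for three published
dataset preparations ship as named presets.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml


class InputError(ValueError):
    """Missing or unusable input file."""


class FormatError(ValueError):
    """Input present but malformed (e.g. non-integer counts)."""


# --------------------------------------------------------------------------
# Core container
# --------------------------------------------------------------------------

@dataclass
class UMIMatrix:
    """Sparse cells x genes matrix of UMI counts with axis names.

    Invariants: counts are integers >= 0; ``cell_ids`` and ``gene_ids`` are
    unique and match the matrix dimensions.
    """

    X: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X))
        self.X = self.X.tocsr()
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if not np.issubdtype(self.X.dtype, np.integer):
            data = self.X.data
            if data.size and not np.allclose(data, np.rint(data)):
                bad = int(np.argmin(np.isclose(data, np.rint(data))))
                raise FormatError(f"non-integer count value {data[bad]!r} in matrix")
            self.X = self.X.astype(np.int64)
        if self.X.nnz and self.X.data.min() < 0:
            raise FormatError("negative count values in matrix")
        for name, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} identifiers")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def gene_totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "UMIMatrix":
        index = np.asarray(index)
        return UMIMatrix(self.X[index], self.cell_ids[index], self.gene_ids)

    def subset_genes(self, index: np.ndarray) -> "UMIMatrix":
        index = np.asarray(index)
        return UMIMatrix(self.X[:, index].tocsr(), self.cell_ids, self.gene_ids[index])

    def gene_index(self, names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[n] for n in names if n in lookup], dtype=np.int64)

    # -- AnnData bridge -----------------------------------------------------

    def to_anndata(self):
        import anndata

        return anndata.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids.astype(str), name="gene")),
        )

    @classmethod
    def from_anndata(cls, adata) -> "UMIMatrix":
        X = adata.X
        if not sp.issparse(X):
            X = sp.csr_matrix(np.asarray(X))
        return cls(X.tocsr(), np.asarray(adata.obs_names), np.asarray(adata.var_names))


@dataclass
class CellSizes:
    """Per-cell UMI totals and the metacell size thresholds derived from them.

    ``u_capped`` caps each cell at twice the median total so a few very deep
    cells cannot dominate metacell sizing.  ``U_low``/``U_high`` bracket the
    allowed metacell UMI total around the target.
    """

    u: np.ndarray
    u_capped: np.ndarray
    U_targ: int
    U_low: float
    U_high: float

    @classmethod
    def from_totals(cls, u: np.ndarray, target_umis: int,
                    min_cells_per_metacell: int = 12) -> "CellSizes":
        u = np.asarray(u, dtype=np.float64)
        if u.size == 0:
            raise InputError("cannot size metacells with zero cells")
        med = float(np.median(u))
        target = float(target_umis)
        # raise the target beyond the user request if it implies fewer than
        # min_cells_per_metacell cells per metacell on average
        if med > 0 and target / med < min_cells_per_metacell:
            target = min_cells_per_metacell * med
        u_capped = np.minimum(u, 2.0 * med)
        return cls(u=u, u_capped=u_capped, U_targ=int(round(target)),
                   U_low=target / 2.0, U_high=2.0 * target)


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

MITO_PREFIXES = ("MT-",)  # matched case-insensitively


@dataclass
class FilterRecipe:
    """Gene/cell exclusion rules applied before any analysis."""

    excluded_gene_names: frozenset = frozenset()
    exclude_mitochondrial: bool = True
    min_cell_umis: int = 0
    max_cell_umis: float = float("inf")
    max_excluded_fraction: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.excluded_gene_names = frozenset(self.excluded_gene_names)
        if self.min_cell_umis > self.max_cell_umis:
            raise ValueError("min_cell_umis must not exceed max_cell_umis")
        if not (0.0 <= self.max_excluded_fraction <= 1.0):
            raise ValueError("max_excluded_fraction must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "FilterRecipe":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            excluded_gene_names=frozenset(raw.get("excluded_gene_names", ())),
            exclude_mitochondrial=bool(raw.get("exclude_mitochondrial", True)),
            min_cell_umis=int(raw.get("min_cell_umis", 0)),
            max_cell_umis=float(raw.get("max_cell_umis", float("inf"))),
            max_excluded_fraction=float(raw.get("max_excluded_fraction", 1.0)),
            name=str(raw.get("name", Path(path).stem)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "name": self.name,
            "excluded_gene_names": sorted(self.excluded_gene_names),
            "exclude_mitochondrial": self.exclude_mitochondrial,
            "min_cell_umis": self.min_cell_umis,
            "max_cell_umis": self.max_cell_umis,
            "max_excluded_fraction": self.max_excluded_fraction,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


# Published dataset preparations, as configurable presets.
RECIPES: dict[str, FilterRecipe] = {
    "pbmc": FilterRecipe(
        excluded_gene_names=frozenset(
            {"IGHMBP2", "IGLL1", "IGLL5", "IGLON5", "NEAT1", "TMSB10", "TMSB4X"}
        ),
        exclude_mitochondrial=True,
        min_cell_umis=800,
        max_cell_umis=8000,
        max_excluded_fraction=0.10,
        name="pbmc",
    ),
    "hca_bm": FilterRecipe(
        excluded_gene_names=frozenset({"MALAT1", "XIST"}),
        exclude_mitochondrial=True,
        min_cell_umis=800,
        max_cell_umis=25_000,
        max_excluded_fraction=0.30,
        name="hca_bm",
    ),
    "moca": FilterRecipe(
        excluded_gene_names=frozenset(
            {
                "Malat1", "Neat1",
                "1700007G11Rik", "1700019B21Rik", "Cmtm8", "Col4a4", "Fem1b",
                "Gm11375", "Gm28826", "Gm43298", "Kyat3", "Lancl2", "Minpp1",
                "Olfr1062", "Parn", "Poldip3", "Sirpb1b", "Syt16", "Vmn2r-ps49",
            }
        ),
        exclude_mitochondrial=True,
        min_cell_umis=300,
        max_cell_umis=3000,
        max_excluded_fraction=0.20,
        name="moca",
    ),
}


@dataclass
class FilterReport:
    """Exact accounting of what a recipe removed."""

    n_genes_before: int
    n_cells_before: int
    removed_gene_names: list = field(default_factory=list)
    removed_cell_ids: list = field(default_factory=list)
    n_all_zero_genes: int = 0
    n_named_excluded_genes: int = 0
    n_mitochondrial_genes: int = 0
    n_cells_low_umis: int = 0
    n_cells_high_umis: int = 0
    n_cells_excluded_fraction: int = 0

    @property
    def n_genes_removed(self) -> int:
        return len(self.removed_gene_names)

    @property
    def n_cells_removed(self) -> int:
        return len(self.removed_cell_ids)


def _is_mitochondrial(gene_ids: np.ndarray) -> np.ndarray:
    upper = np.array([str(g).upper() for g in gene_ids])
    mask = np.zeros(len(upper), dtype=bool)
    for prefix in MITO_PREFIXES:
        mask |= np.char.startswith(upper, prefix)
    return mask


def apply_filter_recipe(m: UMIMatrix, recipe: FilterRecipe) -> tuple[UMIMatrix, FilterReport]:
    """Remove excluded genes and out-of-bounds cells; return the result and a report.

    The excluded-UMI-fraction test for each cell uses the cell's total over
    *all* genes (before gene removal) as the denominator: genes are marked
    first, then cells are tested on the UMIs they carry in marked genes.
    """
    report = FilterReport(n_genes_before=m.n_genes, n_cells_before=m.n_cells)

    gene_totals = m.gene_totals()
    all_zero = gene_totals == 0
    named = np.isin(m.gene_ids.astype(str), list(recipe.excluded_gene_names))
    mito = _is_mitochondrial(m.gene_ids) if recipe.exclude_mitochondrial else np.zeros(m.n_genes, bool)
    removed_genes = all_zero | named | mito
    report.n_all_zero_genes = int(all_zero.sum())
    report.n_named_excluded_genes = int(named.sum())
    report.n_mitochondrial_genes = int(mito.sum())
    report.removed_gene_names = list(m.gene_ids[removed_genes])

    totals = m.cell_totals().astype(np.float64)
    excluded_umis = np.asarray(m.X[:, removed_genes].sum(axis=1)).ravel().astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        excluded_frac = np.where(totals > 0, excluded_umis / totals, 0.0)

    low = totals < recipe.min_cell_umis
    high = totals > recipe.max_cell_umis
    frac_bad = excluded_frac > recipe.max_excluded_fraction
    removed_cells = low | high | frac_bad
    report.n_cells_low_umis = int(low.sum())
    report.n_cells_high_umis = int(high.sum())
    report.n_cells_excluded_fraction = int(frac_bad.sum())
    report.removed_cell_ids = list(m.cell_ids[removed_cells])

    if removed_cells.all():
        raise InputError(
            "filter recipe removed every cell; review the UMI bounds "
            f"({recipe.min_cell_umis}..{recipe.max_cell_umis}) and the "
            f"excluded-fraction cap ({recipe.max_excluded_fraction})"
        )

    kept = m.subset_cells(np.flatnonzero(~removed_cells)).subset_genes(np.flatnonzero(~removed_genes))
    return kept, report


# --------------------------------------------------------------------------
# Downsampling
# --------------------------------------------------------------------------

def choose_downsample_target(totals: np.ndarray, target_umis: int,
                             min_umis: int = 500) -> int:
    """Common per-cell depth for a pile: 5th percentile of totals, clipped.

    The clip keeps the target attainable by most cells while never exceeding
    the metacell UMI target (or dropping below a usable depth).
    """
    totals = np.asarray(totals)
    q5 = float(np.percentile(totals, 5)) if totals.size else float(min_umis)
    lo = min(min_umis, int(totals.max())) if totals.size else min_umis
    return int(np.clip(q5, lo, target_umis))


def downsample_cells(m: UMIMatrix, target: int, seed: int) -> UMIMatrix:
    """Subsample each cell deeper than ``target`` to exactly ``target`` UMIs.

    Molecules are drawn uniformly without replacement (multivariate
    hypergeometric per cell), so expected per-gene counts scale by
    ``target / total``.  Cells at or below the target are unchanged.
    """
    if target < 1:
        raise ValueError("downsampling target must be >= 1")
    rng = np.random.default_rng(seed)
    X = m.X.tocsr().copy()
    totals = np.asarray(X.sum(axis=1)).ravel()
    indptr, data = X.indptr, X.data
    new_data = data.copy()
    for row in np.flatnonzero(totals > target):
        lo, hi = indptr[row], indptr[row + 1]
        colors = data[lo:hi].astype(np.int64)
        new_data[lo:hi] = rng.multivariate_hypergeometric(colors, target)
    out = sp.csr_matrix((new_data, X.indices.copy(), indptr.copy()), shape=X.shape)
    out.eliminate_zeros()
    return UMIMatrix(out, m.cell_ids, m.gene_ids)


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def _find_file(directory: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            candidate = directory / (stem + suffix)
            if candidate.exists():
                return candidate
    raise InputError(f"none of {stems} found in {directory}")


def _read_tsv_column(path: Path, column: int = 0) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    values = []
    with opener(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            values.append(fields[min(column, len(fields) - 1)])
    return np.asarray(values, dtype=object)


def load_umi_matrix(path, fmt: str | None = None) -> UMIMatrix:
    """Read a UMI matrix from an MTX directory or an AnnData-layout HDF5 file.

    Counts are returned cells x genes regardless of the on-disk orientation
    (10x Matrix Market files are conventionally genes x cells).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such path: {path}")
    if fmt is None:
        fmt = "mtx_dir" if path.is_dir() else "h5"

    if fmt == "mtx_dir":
        mtx_path = _find_file(path, ("matrix.mtx",))
        barcodes = _read_tsv_column(_find_file(path, ("barcodes.tsv",)))
        # 10x ships either 2-column genes.tsv or 3-column features.tsv;
        # column 0 (the stable id) may repeat, so prefer unique symbols.
        feat_path = _find_file(path, ("features.tsv", "genes.tsv"))
        features = _read_tsv_column(feat_path, column=1)
        if len(set(features)) != len(features):
            features = _read_tsv_column(feat_path, column=0)
        try:
            raw = scipy.io.mmread(str(mtx_path))
        except ValueError as exc:
            raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
        raw = sp.csr_matrix(raw)
        if raw.shape == (len(features), len(barcodes)):
            raw = raw.T.tocsr()  # genes x cells on disk -> cells x genes
        elif raw.shape != (len(barcodes), len(features)):
            raise FormatError(
                f"matrix shape {raw.shape} matches neither orientation of "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        if raw.shape[0] == 0 or raw.shape[1] == 0:
            raise FormatError("empty matrix")
        return UMIMatrix(raw, barcodes, features)

    if fmt == "h5":
        import anndata

        return UMIMatrix.from_anndata(anndata.read_h5ad(path))

    raise ValueError(f"unknown format {fmt!r}")


def save_umi_matrix(m: UMIMatrix, path, fmt: str = "mtx_dir") -> None:
    """Write cells x genes counts as an MTX directory or an h5ad file."""
    path = Path(path)
    if fmt == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), m.X.T.tocoo())  # genes x cells
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(str(c) for c in m.cell_ids) + "\n")
        with open(path / "features.tsv", "w") as fh:
            for g in m.gene_ids:
                fh.write(f"{g}\t{g}\tGene Expression\n")
    elif fmt == "h5":
        m.to_anndata().write_h5ad(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
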
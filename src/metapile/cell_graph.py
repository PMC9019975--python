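"""Per-pile feature gene election and balanced K-nn graph construction.

Feature genes are selected independently within each pile (on cells
downsampled to a common depth), so late piles of similar cells can focus on
genes separating sub-types.  The cell-cell similarity graph is *balanced*:
raw Pearson similarities are replaced by the geometric mean of the two
directed similarity ranks, which suppresses hub cells, and in/out degrees
are capped at 3K and K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .config import FeatureParams, GraphParams
from .data_io import UMIMatrix


class FeatureSelectionError(ValueError):
    """No gene passed the feature criteria; the pile is unpartitionable."""


@dataclass
class FeatureSelection:
    """Elected feature genes plus per-gene diagnostics."""

    feature_genes: np.ndarray          # gene indices into the pile matrix
    normalized_variance: np.ndarray    # var/mean per gene (downsampled counts)
    total_umis: np.ndarray
    expressing_cells: np.ndarray       # cells with >= min_umis_per_cell UMIs
    forbidden_genes: frozenset = frozenset()


def select_features(m: UMIMatrix, forbidden: frozenset = frozenset(),
                    params: FeatureParams | None = None) -> FeatureSelection:
    """Elect feature genes for one (downsampled) pile.

    A gene qualifies iff it is not forbidden, its normalized variance
    (variance/mean) exceeds the median of the ``expression_window`` genes of
    most similar mean expression by at least ``normalized_variance_gap``,
    it has at least ``min_gene_total_umis`` UMIs in the pile, and at least
    ``min_umis_per_cell`` UMIs in each of ``min_expressing_cells`` cells.
    """
    params = params or FeatureParams()
    if m.n_cells < 2:
        raise FeatureSelectionError("need at least two cells to select features")
    X = m.X.tocsc()
    n = m.n_cells

    totals = np.asarray(X.sum(axis=0)).ravel().astype(np.float64)
    mean = totals / n
    sq = np.asarray(X.multiply(X).sum(axis=0)).ravel().astype(np.float64)
    var = sq / n - mean**2
    with np.errstate(divide="ignore", invalid="ignore"):
        norm_var = np.where(mean > 0, var / mean, 0.0)

    strong = X.copy()
    strong.data = (strong.data >= params.min_umis_per_cell).astype(np.int64)
    expressing = np.asarray(strong.sum(axis=0)).ravel()

    # median normalized variance among the window of most similar mean
    # expression, via a sliding window over the mean-sorted gene order
    order = np.argsort(mean, kind="stable")
    nv_sorted = norm_var[order]
    half = params.expression_window // 2
    local_median = np.empty(m.n_genes)
    for pos in range(m.n_genes):
        lo = max(0, pos - half)
        hi = min(m.n_genes, lo + params.expression_window)
        lo = max(0, hi - params.expression_window)
        local_median[pos] = np.median(nv_sorted[lo:hi])
    baseline = np.empty(m.n_genes)
    baseline[order] = local_median

    is_forbidden = np.isin(m.gene_ids.astype(str), list(forbidden))
    mask = (
        ~is_forbidden
        & (norm_var >= baseline + params.normalized_variance_gap)
        & (totals >= params.min_gene_total_umis)
        & (expressing >= params.min_expressing_cells)
    )
    features = np.flatnonzero(mask)
    if features.size == 0:
        raise FeatureSelectionError(
            "no feature genes passed the selection thresholds; relax "
            "normalized_variance_gap or the UMI requirements"
        )
    return FeatureSelection(
        feature_genes=features,
        normalized_variance=norm_var,
        total_umis=totals,
        expressing_cells=expressing,
        forbidden_genes=frozenset(forbidden),
    )


def choose_K(u: np.ndarray, target_umis: int) -> int:
    """Neighbor budget: median number of cells needed to reach the UMI target."""
    u = np.asarray(u, dtype=np.float64)
    if u.size == 0:
        raise ValueError("no cells")
    med = float(np.median(u))
    if med <= 0:
        return 1
    return max(1, int(math.ceil(target_umis / med)))


@dataclass
class WeightedCellGraph:
    """Directed weighted K-nn graph over the cells of one pile.

    ``out_csr[i, j] = w`` is the edge i -> j.  Out-degrees are <= K and
    in-degrees <= 3K; weights lie in (0, 1].
    """

    out_csr: sp.csr_matrix
    K: int
    isolated: np.ndarray  # cells flagged as having no usable feature signal

    def __post_init__(self) -> None:
        self.out_csr = self.out_csr.tocsr()
        self.in_csr = self.out_csr.T.tocsr()

    @property
    def n_nodes(self) -> int:
        return self.out_csr.shape[0]

    @property
    def n_edges(self) -> int:
        return self.out_csr.nnz

    def symmetric(self) -> sp.csr_matrix:
        """Undirected view: w(i,j) + w(j,i)."""
        return (self.out_csr + self.in_csr).tocsr()

    def to_edge_frame(self, cell_ids: np.ndarray | None = None):
        import pandas as pd

        coo = self.out_csr.tocoo()
        src, targ = coo.row, coo.col
        if cell_ids is not None:
            src, targ = cell_ids[src], cell_ids[targ]
        return pd.DataFrame({"src_cell": src, "targ_cell": targ, "weight": coo.data})


def _rank_matrix(S: np.ndarray) -> np.ndarray:
    """Outgoing rank values: the most similar neighbor of each cell gets the
    highest value (n-1), the least similar gets 1, self gets 0.

    Ties are broken toward the lower cell index for determinism.  Rows are
    processed in chunks to bound the int64 argsort scratch space.
    """
    n = S.shape[0]
    R = np.empty((n, n), dtype=np.float32)
    rank_values = np.arange(n - 1, -1, -1, dtype=np.float32)
    chunk = max(1, min(n, 16_000_000 // max(n, 1)))
    neg = -S
    np.fill_diagonal(neg, np.inf)  # self sorts last -> rank value 0
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        order = np.argsort(neg[lo:hi], axis=1, kind="stable")
        np.put_along_axis(R[lo:hi], order, rank_values[None, :], axis=1)
    return R


def _corr_rows(F: np.ndarray) -> np.ndarray:
    """Row-row Pearson correlation in float32 (cells x features input)."""
    Z = F - F.mean(axis=1, keepdims=True)
    norm = np.sqrt((Z * Z).sum(axis=1, keepdims=True))
    bad = norm[:, 0] == 0
    norm[bad] = 1.0
    Z /= norm
    S = Z @ Z.T
    np.clip(S, -1.0, 1.0, out=S)
    if bad.any():
        S[bad, :] = np.nan
        S[:, bad] = np.nan
    return S


def _cap_rows(B: np.ndarray, cap: int) -> None:
    """Zero all but the ``cap`` largest entries of each row, in place."""
    n = B.shape[1]
    if cap >= n:
        return
    chunk = max(1, min(B.shape[0], 16_000_000 // max(n, 1)))
    for lo in range(0, B.shape[0], chunk):
        hi = min(B.shape[0], lo + chunk)
        block = B[lo:hi]
        keep_idx = np.argpartition(block, n - cap, axis=1)[:, n - cap:]
        kept = np.take_along_axis(block, keep_idx, axis=1).copy()
        block[:] = 0.0
        np.put_along_axis(block, keep_idx, kept, axis=1)


def build_balanced_knn(m: UMIMatrix, feature_genes: np.ndarray, K: int,
                       params: GraphParams | None = None) -> WeightedCellGraph:
    """Balanced K-nn graph from feature-gene correlations.

    Steps: Pearson correlation of log2(count+1) over feature genes; directed
    similarity ranks (strongest neighbor = highest value); balanced rank
    B = sqrt(R * R^T); keep the strongest ~sqrt(10)*K candidates per cell;
    cap in-degree at 3K, then out-degree at K; scale weights into (0, 1].
    Cells with no feature UMIs become isolated nodes.
    """
    params = params or GraphParams()
    n = m.n_cells
    if n < 2:
        raise ValueError("need at least two cells to build a graph")
    if len(feature_genes) == 0:
        raise ValueError("need at least one feature gene")
    K = min(K, n - 1)

    F = np.log2(m.X[:, feature_genes].toarray().astype(np.float32) + 1.0)
    isolated = np.flatnonzero(np.asarray(m.X[:, feature_genes].sum(axis=1)).ravel() == 0)

    S = _corr_rows(F)
    S[~np.isfinite(S)] = -2.0  # zero-variance cells rank below any real similarity
    if isolated.size:
        S[isolated, :] = -2.0
        S[:, isolated] = -2.0

    R = _rank_matrix(S)
    B = np.sqrt(R * R.T)
    np.fill_diagonal(B, 0.0)
    if isolated.size:
        B[isolated, :] = 0.0
        B[:, isolated] = 0.0

    _cap_rows(B, int(math.ceil(params.balance_prune_factor * K)))  # pre-prune
    Bt = np.ascontiguousarray(B.T)
    _cap_rows(Bt, params.max_incoming_factor * K)                  # in-degree cap
    B = np.ascontiguousarray(Bt.T)
    _cap_rows(B, K)                                                # out-degree cap

    top = B.max()
    if top > 0:
        B /= top
    out = sp.csr_matrix(B)
    out.eliminate_zeros()
    out = out.astype(np.float64)
    return WeightedCellGraph(out_csr=out, K=K, isolated=isolated)
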
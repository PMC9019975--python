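"""Adaptive deviant (outlier) cell detection.

A metacell should hold cells drawn from one multinomial profile.  A cell is
*deviant* when at least one gene is severely over-expressed relative to the
pooled profile of its metacell.  Two thresholds are tuned adaptively rather
than fixed, which prevents noisy datasets from dissolving wholesale:

* ``T_fold`` — the minimal (linear) fold factor making a gene deviant;
  starts at 8 and doubles while more than 3% of genes are deviant.
* ``T_N`` — the maximal number of cells that may be removed due to any
  single gene; starts at 1 and doubles while the flagged cells stay within
  25% of the pile.

Cells are scored by the minimal rank of their fold factors over deviant
genes (rank 1 = most extreme per gene); a cell is removed when that minimal
rank is at most ``T_N``, which by construction bounds per-gene removals at
``T_N``.  Removal iterates (profiles are recomputed) until stable or the
cumulative 25% cap is reached, after which undersized metacells dissolve
into outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import DeviantParams, PartitionParams
from .data_io import CellSizes
from .partition import OUTLIER, _marker_metacells, compact_labels


@dataclass
class FoldFactors:
    """Sparse observed/expected fold factors (only where counts are nonzero).

    Entries at zero observed counts have fold <= 1 and can never trip the
    deviance threshold, so only nonzero entries are materialized; the dense
    fold for any (cell, gene) can be reconstructed from ``expected_scale``.
    """

    folds: sp.csr_matrix          # cells x genes, (x+1)/(e+1) at nonzero x
    expected_fraction: np.ndarray  # per-metacell gene fractions, M x genes
    cell_totals: np.ndarray
    mc: np.ndarray

    def dense_gene_column(self, gene: int) -> np.ndarray:
        """Fold factors of every cell for one gene (including zero counts)."""
        expected = np.ones(len(self.mc))
        valid = self.mc >= 0
        expected[valid] = self.expected_fraction[self.mc[valid], gene] * \
            self.cell_totals[valid]
        base = 1.0 / (expected + 1.0)
        col = np.asarray(self.folds[:, gene].todense()).ravel()
        out = np.where(col > 0, col, base)
        out[~valid] = 0.0
        return out


def compute_fold_factors(counts: sp.csr_matrix, mc: np.ndarray) -> FoldFactors:
    """Fold factor of each observed count against its metacell's pooled profile.

    The expectation for cell c and gene g is the metacell's pooled gene
    fraction scaled to the cell's total; folds are regularized as
    (x+1)/(expected+1).  Cells of singleton metacells and outliers get
    fold 1 everywhere (no usable comparison).
    """
    counts = counts.tocsr()
    n, G = counts.shape
    mc = np.asarray(mc, dtype=np.int64)
    valid = mc >= 0
    M = int(mc[valid].max()) + 1 if valid.any() else 0
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(np.float64)

    pooled = np.zeros((M, G))
    if M:
        ind = sp.csr_matrix(
            (np.ones(valid.sum()), (mc[valid], np.flatnonzero(valid))),
            shape=(M, n),
        )
        pooled = np.asarray((ind @ counts).todense(), dtype=np.float64)
    pooled_tot = pooled.sum(axis=1, keepdims=True)
    pooled_tot[pooled_tot == 0] = 1.0
    fraction = pooled / pooled_tot

    members = np.bincount(mc[valid], minlength=M) if M else np.zeros(0, int)
    singleton = np.zeros(n, dtype=bool)
    if M:
        singleton[valid] = members[mc[valid]] <= 1

    coo = counts.tocoo()
    folds = np.ones(coo.nnz)
    ok = valid[coo.row] & ~singleton[coo.row]
    exp = np.zeros(coo.nnz)
    exp[ok] = fraction[mc[coo.row[ok]], coo.col[ok]] * totals[coo.row[ok]]
    folds[ok] = (coo.data[ok] + 1.0) / (exp[ok] + 1.0)
    out = sp.csr_matrix((folds, (coo.row, coo.col)), shape=(n, G))
    return FoldFactors(out, fraction, totals, mc)


@dataclass
class DeviantCall:
    deviant_cells: np.ndarray
    T_fold: float
    T_N: int
    deviant_genes: np.ndarray
    per_gene_removals: dict = field(default_factory=dict)
    records: list = field(default_factory=list)   # (cell, gene, fold, rank)


def _deviant_genes_at(ff: FoldFactors, T_fold: float) -> np.ndarray:
    if ff.folds.nnz == 0:
        return np.empty(0, np.int64)
    gene_max = ff.folds.max(axis=0).toarray().ravel()
    return np.flatnonzero(gene_max >= T_fold)


def detect_deviants(ff: FoldFactors, params: DeviantParams | None = None
                    ) -> DeviantCall:
    """Tune (T_fold, T_N) and call deviant cells via the min-rank scheme."""
    params = params or DeviantParams()
    n_cells, n_genes = ff.folds.shape
    active = ff.mc >= 0
    n_active = int(active.sum())

    # T_fold: smallest doubling of the baseline with <= 3% deviant genes
    T_fold = params.fold_baseline
    while True:
        dev_genes = _deviant_genes_at(ff, T_fold)
        if dev_genes.size <= params.max_deviant_gene_fraction * n_genes:
            break
        T_fold *= 2.0
        if T_fold > 2.0**30:
            break
    if dev_genes.size == 0:
        return DeviantCall(np.empty(0, np.int64), T_fold,
                           params.cells_per_gene_baseline, dev_genes)

    # per deviant gene: rank the cells whose fold reaches T_fold by
    # descending fold (rank 1 = most extreme, ties -> lower cell index);
    # a cell's score is its minimal rank over deviant genes
    NO_RANK = n_cells + 1
    min_rank = np.full(n_cells, NO_RANK, dtype=np.int64)
    best_gene = np.full(n_cells, -1, dtype=np.int64)
    best_fold = np.zeros(n_cells)
    for g in dev_genes:
        col = ff.dense_gene_column(int(g))
        qualifying = np.flatnonzero((col >= T_fold) & active)
        order = qualifying[np.argsort(-col[qualifying], kind="stable")]
        ranks = np.arange(1, len(order) + 1)
        improved = ranks < min_rank[order]
        upd = order[improved]
        min_rank[upd] = ranks[improved]
        best_gene[upd] = g
        best_fold[upd] = col[upd]

    # T_N: largest doubling of the baseline keeping deviants within 25% of cells
    cap = params.max_deviant_cell_fraction * n_active
    T_N = params.cells_per_gene_baseline
    while True:
        candidate = T_N * 2
        if candidate > n_cells:
            break
        n_at = int((min_rank <= candidate).sum())
        if n_at > cap:
            break
        T_N = candidate
        if n_at == int((min_rank < NO_RANK).sum()):
            break  # every qualifying cell already covered
    deviant = np.flatnonzero(min_rank <= T_N)
    if deviant.size > cap:  # baseline itself violates the cap: trim by rank
        order = np.argsort(min_rank[deviant], kind="stable")
        deviant = np.sort(deviant[order[: int(cap)]])

    per_gene: dict[int, int] = {}
    records = []
    for c in deviant:
        g = int(best_gene[c])
        per_gene[g] = per_gene.get(g, 0) + 1
        records.append((int(c), g, float(best_fold[c]), int(min_rank[c])))
    return DeviantCall(deviant, T_fold, T_N, dev_genes, per_gene, records)


@dataclass
class DeviantReport:
    rounds: list = field(default_factory=list)    # DeviantCall per iteration
    dissolved_metacells: int = 0

    def to_frame(self, cell_ids=None, gene_ids=None) -> pd.DataFrame:
        rows = []
        for it, call in enumerate(self.rounds):
            for cell, gene, fold, rank in call.records:
                rows.append({
                    "cell_id": cell_ids[cell] if cell_ids is not None else cell,
                    "gene": gene_ids[gene] if gene_ids is not None else gene,
                    "fold": fold,
                    "rank": rank,
                    "iteration": it,
                })
        return pd.DataFrame(rows, columns=["cell_id", "gene", "fold", "rank", "iteration"])


def iterate_deviant_removal(
    counts: sp.csr_matrix,
    mc: np.ndarray,
    u: np.ndarray,
    target_umis: int,
    params: DeviantParams | None = None,
    partition_params: PartitionParams | None = None,
) -> tuple[np.ndarray, DeviantReport]:
    """Remove deviant cells iteratively, then dissolve undersized metacells.

    Each round recomputes pooled profiles from the surviving members; the
    loop ends when a round flags nothing new or the cumulative removals
    reach 25% of the pile.  Metacells left below the minimum size (cells or
    capped UMIs, with the marker-gene exemption) dissolve entirely; all
    removed cells are marked outliers in the returned assignment.
    """
    params = params or DeviantParams()
    partition_params = partition_params or PartitionParams()
    mc = np.asarray(mc, dtype=np.int64).copy()
    n = len(mc)
    budget = int(np.floor(params.max_deviant_cell_fraction * n))
    removed_total = 0
    report = DeviantReport()

    if params.enabled:
        for _ in range(n):  # each round removes >= 1 cell, so this terminates
            ff = compute_fold_factors(counts, mc)
            call = detect_deviants(ff, params)
            new = call.deviant_cells[mc[call.deviant_cells] >= 0]
            if new.size == 0:
                break
            if removed_total + new.size > budget:
                keep = budget - removed_total
                order = np.argsort([r[3] for r in call.records])  # by rank
                ranked = np.asarray([call.records[i][0] for i in order])
                new = ranked[np.isin(ranked, new)][:keep]
            if new.size == 0:
                break
            mc[new] = OUTLIER
            removed_total += int(new.size)
            report.rounds.append(call)
            if removed_total >= budget:
                break

    # dissolve metacells that ended up too small
    sizes = CellSizes.from_totals(u, target_umis, partition_params.min_metacell_cells)
    valid = mc >= 0
    if valid.any():
        M = int(mc[valid].max()) + 1
        totals = np.bincount(mc[valid], weights=sizes.u_capped[valid], minlength=M)
        members = np.bincount(mc[valid], minlength=M)
        marker = _marker_metacells(counts, mc, partition_params.marker_fold)
        if marker.size < M:
            marker = np.pad(marker, (0, M - marker.size))
        threshold = np.where(marker, 0.5 * sizes.U_low, sizes.U_low)
        bad = ((totals <= threshold) | (members < partition_params.min_metacell_cells)) \
            & (members > 0)
        dissolved = np.flatnonzero(np.isin(mc, np.flatnonzero(bad)))
        if dissolved.size:
            mc[dissolved] = OUTLIER
            report.dissolved_metacells = int(bad.sum())
    return compact_labels(mc), report
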
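"""Rare gene module detection.

Cell states present at frequencies far below one per pile cannot survive
random piling: their handful of cells is scattered and absorbed as noise.
This pre-process scans the *whole* matrix for small groups of mutually
correlated, rarely expressed genes ("rare gene modules"), collects the cells
expressing each module, and hands those cells to the caller as dedicated
piles that bypass random piling.

Pipeline: rare-gene screen -> second-order gene correlation -> Ward
clustering -> maximal qualifying subtrees -> enrichment-based expansion ->
module cell sets with size guards (at least 12 cells, at most the number
expected to contribute ~48 cells to a random pile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.sparse as sp

from scipy import ndimage

from .config import RareModuleParams
from .data_io import UMIMatrix


@dataclass
class RareGeneModule:
    """A rare gene module: seed genes, expanded genes, and its cell set."""

    seed_genes: np.ndarray                  # gene indices from clustering
    expanded_genes: np.ndarray              # superset after enrichment expansion
    cells: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))  # C^M
    discarded: bool = False
    discard_reason: str = ""                # "" | "too_few" | "too_common"

    def __post_init__(self) -> None:
        self.seed_genes = np.asarray(self.seed_genes, dtype=np.int64)
        self.expanded_genes = np.asarray(self.expanded_genes, dtype=np.int64)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if not set(self.seed_genes).issubset(set(self.expanded_genes)):
            raise ValueError("seed genes must be contained in expanded genes")


def find_rare_genes(m: UMIMatrix, params: RareModuleParams) -> np.ndarray:
    """Genes seen in <= ``max_cell_fraction`` of cells yet abundantly in one.

    Returns gene indices, ascending.  Works from the CSR arrays directly so
    no column-major copy of the (possibly huge) matrix is materialized.
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty matrix")
    X = m.X.tocsr()
    expressing = np.bincount(X.indices, minlength=m.n_genes)
    if X.nnz:
        max_per_cell = ndimage.maximum(X.data, labels=X.indices,
                                       index=np.arange(m.n_genes))
    else:
        max_per_cell = np.zeros(m.n_genes)
    fraction = expressing / m.n_cells
    mask = (fraction <= params.max_cell_fraction) & (max_per_cell >= params.min_max_umis)
    return np.flatnonzero(mask)


def _safe_corrcoef(rows: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; zero-variance pairs -> 0, diag -> 1."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    c = np.atleast_2d(c)
    c[~np.isfinite(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def second_order_correlation(expr: np.ndarray) -> np.ndarray:
    """r2 = cor(cor(expr)): correlation of gene correlation patterns.

    ``expr`` is genes x cells.  Two genes score high when they correlate with
    the *same set of other genes*, which is much more robust for near-binary
    rare-gene vectors than direct correlation.

    Degenerate case: when a gene's correlation row is (near-)constant — e.g.
    every rare gene belongs to one tight module, so all first-order
    correlations are ~1 — its "pattern" carries no signal and cor(r) merely
    amplifies numerical noise.  For pairs involving such genes the
    first-order correlation is used instead.
    """
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape[0] < 2:
        raise ValueError("need at least two rare genes")
    r = _safe_corrcoef(expr)
    r2 = _safe_corrcoef(r)
    informative = r.std(axis=1) > 0.01
    pattern_defined = informative[:, None] & informative[None, :]
    r2 = np.where(pattern_defined, r2, r)
    r2 = (r2 + r2.T) / 2.0
    np.fill_diagonal(r2, 1.0)
    return r2


def candidate_modules(r2: np.ndarray, params: RareModuleParams) -> list[np.ndarray]:
    """Maximal Ward-dendrogram subtrees of >=4 genes with mean r2 >= 0.1.

    Genes are clustered with Ward linkage on (1 - r2) distances.  A subtree
    qualifies when its leaf count reaches ``min_module_genes`` and the mean
    off-diagonal r2 among its leaves reaches ``min_mean_r2``; only subtrees
    not contained in another qualifying subtree are returned.
    """
    n = r2.shape[0]
    if n < params.min_module_genes:
        return []
    dist = 1.0 - r2
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(n, k=1)]
    linkage = sch.linkage(condensed, method="ward")

    # leaves of every internal node
    leaves: list[list[int]] = [[i] for i in range(n)]
    for a, b in linkage[:, :2].astype(int):
        leaves.append(leaves[a] + leaves[b])

    def qualifies(node: int) -> bool:
        members = leaves[node]
        if len(members) < params.min_module_genes:
            return False
        sub = r2[np.ix_(members, members)]
        k = len(members)
        mean_off = (sub.sum() - np.trace(sub)) / (k * (k - 1))
        return mean_off >= params.min_mean_r2

    # keep qualifying nodes with no qualifying ancestor (maximality); walking
    # from the root keeps the larger subtree on ties by construction
    modules: list[np.ndarray] = []
    root = n + len(linkage) - 1
    stack = [root]
    while stack:
        node = stack.pop()
        if qualifies(node):
            modules.append(np.asarray(sorted(leaves[node]), dtype=np.int64))
        elif node >= n:
            a, b = linkage[node - n, :2].astype(int)
            stack.extend((b, a))
    return modules


def _cells_expressing(X: sp.spmatrix, genes: np.ndarray) -> np.ndarray:
    """Indices of cells (rows) with >= 1 UMI over ``genes``."""
    if len(genes) == 0:
        return np.empty(0, np.int64)
    sub = X[:, np.asarray(genes)].tocsr()
    return np.flatnonzero(np.diff(sub.indptr))


def expand_module(module: np.ndarray, m: UMIMatrix, params: RareModuleParams,
                  max_module_cells: int) -> RareGeneModule:
    """Grow a seed module by enriched genes, then collect and vet its cells.

    Let C be the cells with any UMI of the seed genes.  A gene joins when its
    per-UMI frequency inside C is >= ``expansion_fold`` times its frequency
    over all cells, as long as the joined module's expressing-cell count
    stays below ``expansion_cell_growth_cap`` times |C| (greedy, descending
    enrichment).  The module cell set C^M is then every cell with at least
    ``min_module_umis_per_cell`` UMIs over the expanded genes; modules with
    fewer than 12 such cells, or more than ``max_module_cells``, are
    discarded.
    """
    module = np.asarray(module, dtype=np.int64)
    if module.size == 0:
        raise ValueError("empty seed module")
    X = m.X.tocsr()
    cells_C = _cells_expressing(X, module)
    if cells_C.size == 0:
        return RareGeneModule(module, module, np.empty(0, np.int64),
                              discarded=True, discard_reason="too_few")

    sub_C = m.X[cells_C]  # csr rows of C
    gene_umis_C = np.asarray(sub_C.sum(axis=0)).ravel().astype(np.float64)
    total_C = gene_umis_C.sum()
    gene_umis_all = m.gene_totals().astype(np.float64)
    total_all = gene_umis_all.sum()

    with np.errstate(divide="ignore", invalid="ignore"):
        freq_C = gene_umis_C / total_C
        freq_all = gene_umis_all / total_all
        enrichment = np.where(gene_umis_C > 0, freq_C / freq_all, 0.0)

    candidates = np.flatnonzero(enrichment >= params.expansion_fold)
    candidates = candidates[~np.isin(candidates, module)]
    candidates = candidates[np.argsort(-enrichment[candidates], kind="stable")]

    expanded = list(module)
    expressing = set(cells_C.tolist())
    cap = params.expansion_cell_growth_cap * cells_C.size
    if candidates.size:
        cand_cols = X[:, candidates].tocsc()  # few columns: cheap to slice
        for j, g in enumerate(candidates):
            gained = cand_cols.indices[cand_cols.indptr[j]: cand_cols.indptr[j + 1]]
            new_expressing = expressing | set(gained.tolist())
            if len(new_expressing) < cap:
                expanded.append(int(g))
                expressing = new_expressing
    expanded = np.asarray(sorted(expanded), dtype=np.int64)

    module_umis = np.asarray(X[:, expanded].sum(axis=1)).ravel()
    cells_CM = np.flatnonzero(module_umis >= params.min_module_umis_per_cell)

    result = RareGeneModule(module, expanded, cells_CM)
    if cells_CM.size < params.min_module_cells:
        result.discarded, result.discard_reason = True, "too_few"
    elif cells_CM.size > max_module_cells:
        result.discarded, result.discard_reason = True, "too_common"
    return result


def detect_rare_modules(
    m: UMIMatrix,
    params: RareModuleParams,
    pile_size: int,
) -> tuple[list[RareGeneModule], np.ndarray]:
    """Full pre-process: returns kept modules and a per-cell module assignment.

    The assignment array holds -1 for cells in no module; cells claimed by
    several modules go to the one where they carry the most module UMIs
    (ties to the lower module index).  The upper cell bound T is the count
    expected to land ~``pile_target_cells`` members in one random pile:
    T = pile_target_cells * n_cells / pile_size.
    """
    assignment = np.full(m.n_cells, -1, dtype=np.int64)
    X = m.X.tocsr()
    rare_genes = find_rare_genes(m, params)
    if rare_genes.size < params.min_module_genes:
        return [], assignment

    max_module_cells = int(np.ceil(params.pile_target_cells * m.n_cells / pile_size))

    # correlations on log2(count+1) restricted to cells expressing any rare gene
    sub = X[:, rare_genes].tocsr()
    active_cells = np.flatnonzero(np.diff(sub.indptr))
    if active_cells.size < 2:
        return [], assignment
    expr = np.log2(sub[active_cells].toarray().T + 1.0)

    r2 = second_order_correlation(expr)
    seeds = candidate_modules(r2, params)

    kept: list[RareGeneModule] = []
    for seed in seeds:
        module = expand_module(rare_genes[seed], m, params, max_module_cells)
        if not module.discarded:
            kept.append(module)
    if not kept:
        return kept, assignment

    # resolve overlaps: each cell goes to the module with its largest
    # module-UMI total (ties -> lower module index)
    best_umis = np.zeros(m.n_cells, dtype=np.int64)
    for idx, module in enumerate(kept):
        umis = np.asarray(X[:, module.expanded_genes].sum(axis=1)).ravel()
        claim = np.zeros(m.n_cells, dtype=bool)
        claim[module.cells] = True
        better = claim & (umis > best_umis) & (assignment == -1)
        # cells already assigned keep their module unless this one is strictly richer
        steal = claim & (umis > best_umis) & (assignment != -1)
        take = better | steal
        assignment[take] = idx
        best_umis[take] = umis[take]
    # rebuild each module's cell set after arbitration
    for idx, module in enumerate(kept):
        module.cells = np.flatnonzero(assignment == idx)
    return kept, assignment


def modules_report(modules: list[RareGeneModule], gene_ids: np.ndarray) -> pd.DataFrame:
    """Tabular summary (one row per module) suitable for TSV export."""
    rows = []
    for i, mod in enumerate(modules):
        rows.append({
            "module_id": i,
            "seed_genes": ";".join(str(gene_ids[g]) for g in mod.seed_genes),
            "expanded_genes": ";".join(str(gene_ids[g]) for g in mod.expanded_genes),
            "n_cells": int(mod.cells.size),
            "status": mod.discard_reason if mod.discarded else "kept",
        })
    return pd.DataFrame(rows, columns=["module_id", "seed_genes", "expanded_genes",
                                       "n_cells", "status"])
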
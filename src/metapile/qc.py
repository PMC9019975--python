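"""Metacell quality metrics and rare-behavior characterization.

The central metric is the *inner normalized variance* (INV): within one
metacell, downsample the member cells to a common depth, compute
variance/mean per gene over the members (genes with at least 40 total UMIs),
and take the 95th percentile over genes.  Under the ideal model — members
sampled i.i.d. from one multinomial — variance/mean is ~1 for every gene,
so INV near 1 indicates a homogeneous metacell and INV well above 1 a mixed
one.

Also provided: size-distribution matching for fair INV comparison between
solutions, a screen for rare marker genes (expressed in one metacell far
above the rest), and per-gene AUROC/fold diagnostics for rare modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_io import UMIMatrix, downsample_cells
from .pipeline import MetacellSolution
from .rare_modules import RareGeneModule

INV_MIN_GENE_UMIS = 40     # genes below this total are too sparse to assess
INV_PERCENTILE = 95.0
QC_DOWNSAMPLE_FLOOR = 100  # do not downsample below this depth


def inner_normalized_variance(members: UMIMatrix, seed: int = 0) -> float:
    """INV of one metacell given its member-cell submatrix.

    Returns NaN when the metacell has fewer than two cells or no gene
    reaches the 40-UMI total after downsampling.
    """
    if members.n_cells < 2:
        return float("nan")
    totals = members.cell_totals()
    target = max(int(totals.min()), QC_DOWNSAMPLE_FLOOR)
    ds = downsample_cells(members, target, seed)
    X = ds.X.tocsc()
    n = ds.n_cells
    gene_tot = np.asarray(X.sum(axis=0)).ravel().astype(np.float64)
    ok = gene_tot >= INV_MIN_GENE_UMIS
    if not ok.any():
        return float("nan")
    mean = gene_tot[ok] / n
    sq = np.asarray(X.multiply(X).sum(axis=0)).ravel().astype(np.float64)[ok]
    var = sq / n - mean**2
    return float(np.percentile(var / mean, INV_PERCENTILE))


@dataclass
class QCReport:
    """Per-metacell INV plus solution-level summaries."""

    inv: np.ndarray                    # per metacell; NaN where undefined
    n_cells: np.ndarray
    umi_totals: np.ndarray
    summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metacell": np.arange(len(self.inv)),
            "inner_normalized_variance": self.inv,
            "n_cells": self.n_cells,
            "umi_total": self.umi_totals,
        })


def qc_report(m: UMIMatrix, solution: MetacellSolution, seed: int = 0) -> QCReport:
    """INV and size bookkeeping for every metacell of a solution."""
    M = solution.n_metacells
    inv = np.full(M, np.nan)
    n_cells = np.zeros(M, dtype=np.int64)
    umis = np.zeros(M, dtype=np.int64)
    for k in range(M):
        idx = solution.members(k)
        n_cells[k] = idx.size
        sub = m.subset_cells(idx)
        umis[k] = int(sub.X.sum())
        inv[k] = inner_normalized_variance(sub, seed=seed + k)
    defined = inv[~np.isnan(inv)]
    summary = {
        "n_metacells": int(M),
        "n_outliers": solution.n_outliers,
        "inv_median": float(np.median(defined)) if defined.size else float("nan"),
        "inv_q25": float(np.percentile(defined, 25)) if defined.size else float("nan"),
        "inv_q75": float(np.percentile(defined, 75)) if defined.size else float("nan"),
    }
    return QCReport(inv, n_cells, umis, summary)


def match_size_distributions(
    solutions: list[tuple[np.ndarray, np.ndarray]],
    seed: int = 0,
) -> list[np.ndarray]:
    """Equalize metacell size distributions across solutions per cell type.

    Each solution is a (cell_metacell, cell_type_label) pair.  Within every
    type, metacells are sorted by size in each solution and rank-matched;
    each matched group is subsampled to the smallest size in its rank.
    Returns adjusted cell_metacell arrays (dropped cells become -1).  Types
    absent from some solution are skipped.
    """
    rng = np.random.default_rng(seed)
    adjusted = [mc.copy() for mc, _ in solutions]
    all_types = set()
    for _, types in solutions:
        all_types.update(np.unique(types).tolist())

    for t in sorted(all_types, key=str):
        per_solution = []
        for mc, types in solutions:
            mask = (types == t) & (mc >= 0)
            labels = np.unique(mc[mask])
            sizes = np.array([(mc[mask] == lab).sum() for lab in labels])
            order = np.argsort(sizes, kind="stable")
            per_solution.append((labels[order], sizes[order]))
        if any(len(labels) == 0 for labels, _ in per_solution):
            continue  # type absent somewhere: skip with no adjustment
        depth = min(len(labels) for labels, _ in per_solution)
        for rank in range(depth):
            target = min(sizes[rank] for _, sizes in per_solution)
            for s, (labels, sizes) in enumerate(per_solution):
                lab = labels[rank]
                mc, types = solutions[s]
                cells = np.flatnonzero((adjusted[s] == lab) & (types == t))
                if cells.size > target:
                    drop = rng.choice(cells, size=cells.size - target, replace=False)
                    adjusted[s][drop] = -1
        # metacells beyond the common depth are left untouched
    return adjusted


def screen_rare_marker_genes(
    solution: MetacellSolution,
    fold: float = 8.0,
    quantile: float = 0.998,
) -> pd.DataFrame:
    """Genes expressed in one metacell ``fold``-fold above almost all others.

    For each gene, its depth-normalized expression in its top metacell is
    compared with the ``quantile`` point of the other metacells' expression;
    genes passing the fold test are returned with their top metacell.
    """
    pooled = np.asarray(solution.pooled.todense(), dtype=np.float64)
    M = pooled.shape[0]
    if M < 2:
        return pd.DataFrame(columns=["gene", "metacell", "top_expression", "background"])
    tot = pooled.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    frac = pooled / tot

    top = np.argmax(frac, axis=0)
    rows = []
    for g in range(frac.shape[1]):
        best = top[g]
        value = frac[best, g]
        if value <= 0:
            continue
        others = np.delete(frac[:, g], best)
        background = np.quantile(others, quantile)
        if value >= fold * max(background, 1e-12) and value > background:
            rows.append({"gene": solution.gene_ids[g], "metacell": int(best),
                         "top_expression": float(value),
                         "background": float(background)})
    return pd.DataFrame(rows, columns=["gene", "metacell", "top_expression", "background"])


def rare_behavior_auroc(
    solution: MetacellSolution,
    module: RareGeneModule,
    m: UMIMatrix,
) -> pd.DataFrame:
    """Per-gene AUROC and fold enrichment for a rare module's cells.

    Positives are the cells of metacells computed from the module's cell
    set; each gene's depth-normalized expression is scored as a classifier
    for those cells.
    """
    positive_mcs = np.unique(solution.cell_metacell[module.cells])
    positive_mcs = positive_mcs[positive_mcs >= 0]
    if positive_mcs.size == 0:
        raise ValueError("the module's cells belong to no metacell")
    positives = np.isin(solution.cell_metacell, positive_mcs)

    totals = m.cell_totals().astype(np.float64)
    totals[totals == 0] = 1.0
    if positives.all():
        raise ValueError("every cell is positive; AUROC undefined")
    labels = positives.astype(int)
    module_genes = set(int(g) for g in module.expanded_genes)
    rows = []
    for g in range(m.n_genes):
        col = np.asarray(m.X[:, g].todense()).ravel() / totals
        if col.max() == 0:
            continue
        auroc = roc_auc_score(labels, col)
        pos_mean = col[positives].mean()
        bg_mean = col[~positives].mean()
        enrichment = (pos_mean + 1e-9) / (bg_mean + 1e-9)
        rows.append({"gene": m.gene_ids[g], "auroc": float(auroc),
                     "fold_enrichment": float(enrichment),
                     "in_module": g in module_genes})
    frame = pd.DataFrame(rows, columns=["gene", "auroc", "fold_enrichment", "in_module"])
    return frame.sort_values("auroc", ascending=False).reset_index(drop=True)


def rare_score_distribution(
    partitioning: np.ndarray,
    module: RareGeneModule,
    m: UMIMatrix,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Module-UMI-fraction scores, the detection threshold, and positives.

    The score of a cell is the fraction of its UMIs coming from the module's
    genes.  The group (metacell/cluster) with the highest mean score sets
    the threshold at 50% of its median member score; every cell at or above
    the threshold (in any group) is a positive.
    """
    totals = m.cell_totals().astype(np.float64)
    totals[totals == 0] = 1.0
    module_umis = np.asarray(m.X[:, module.expanded_genes].sum(axis=1)).ravel()
    scores = module_umis / totals

    labels = np.asarray(partitioning)
    valid = labels >= 0
    if not valid.any() or scores.max() == 0:
        return scores, 0.0, np.empty(0, np.int64)
    groups = np.unique(labels[valid])
    means = np.array([scores[labels == g].mean() for g in groups])
    best = groups[int(np.argmax(means))]
    threshold = 0.5 * float(np.median(scores[labels == best]))
    if threshold <= 0:
        positives = np.flatnonzero(scores > 0)
    else:
        positives = np.flatnonzero(scores >= threshold)
    return scores, threshold, positives
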
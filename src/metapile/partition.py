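"""Graph partitioning with the two-sided stability score.

A partition assigns every cell (node) of a pile's balanced K-nn graph to a
metacell.  Its quality is the *two-sided stability score*: for each node,
the weight fraction of its outgoing (and, separately, incoming) edges that
stay inside its metacell, each divided by the uniform-baseline probability
|M|/|V|, log-transformed, and averaged:

    score(mc) = 1/(2|V|) * sum_v [ log(pstable_in/punif) + log(pstable_out/punif) ]

Unlike modularity-style objectives this penalizes nodes whose internal
connectivity is one-sided (e.g. only outgoing edges into the metacell).
Partitions are produced by seeding, annealed hill climbing over single-node
moves, and three control loops: max-size (dissolve metacells with too many
UMIs), connectivity (min-cut test; disassociate or dissolve weakly attached
parts), and min-size (dissolve undersized metacells, with a marker-gene
exemption at half the usual floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._optimize import _sweep
from .cell_graph import WeightedCellGraph
from .config import PartitionParams
from .data_io import CellSizes

OUTLIER = -1


@dataclass
class StabilityTerms:
    """Per-node pieces of the score, for diagnostics."""

    pstable_out: np.ndarray
    pstable_in: np.ndarray
    punif: np.ndarray
    log_stable_out: np.ndarray
    log_stable_in: np.ndarray
    score: float


@dataclass
class PartitionResult:
    mc: np.ndarray
    warnings: list = field(default_factory=list)

    @property
    def n_metacells(self) -> int:
        valid = self.mc[self.mc >= 0]
        return int(valid.max()) + 1 if valid.size else 0


def compact_labels(mc: np.ndarray) -> np.ndarray:
    """Relabel metacells to a dense 0..M-1 range (outliers stay -1)."""
    mc = np.asarray(mc, dtype=np.int64).copy()
    used = np.unique(mc[mc >= 0])
    remap = {old: new for new, old in enumerate(used)}
    out = mc.copy()
    for i, v in enumerate(mc):
        if v >= 0:
            out[i] = remap[v]
    return out


def _edge_arrays(graph: WeightedCellGraph):
    coo = graph.out_csr.tocoo()
    return coo.row, coo.col, coo.data


def compute_score(graph: WeightedCellGraph, mc: np.ndarray,
                  params: PartitionParams | None = None) -> StabilityTerms:
    """Two-sided stability score plus its per-node terms.

    Outlier nodes (label -1) are excluded from the node set and from edge
    weight sums.  A node side with no internal weight contributes the
    configured floor constant instead of -inf.
    """
    params = params or PartitionParams()
    mc = np.asarray(mc, dtype=np.int64)
    n = graph.n_nodes
    valid = mc >= 0
    V = int(valid.sum())
    if V == 0:
        raise ValueError("cannot score a partition with no assigned nodes")

    src, targ, w = _edge_arrays(graph)
    keep = valid[src] & valid[targ]
    src, targ, w = src[keep], targ[keep], w[keep]
    same = mc[src] == mc[targ]

    wtot_out = np.bincount(src, weights=w, minlength=n)
    win_out = np.bincount(src[same], weights=w[same], minlength=n)
    wtot_in = np.bincount(targ, weights=w, minlength=n)
    win_in = np.bincount(targ[same], weights=w[same], minlength=n)

    sizes = np.bincount(mc[valid])
    punif = np.zeros(n)
    punif[valid] = sizes[mc[valid]] / V

    def side_terms(win, wtot):
        p = np.zeros(n)
        ok = (wtot > 0) & valid
        p[ok] = win[ok] / wtot[ok]
        log_stable = np.full(n, params.log_stability_floor)
        pos = ok & (win > 0)
        log_stable[pos] = np.log(p[pos] / punif[pos])
        log_stable[~valid] = 0.0
        return p, log_stable

    pstable_out, ls_out = side_terms(win_out, wtot_out)
    pstable_in, ls_in = side_terms(win_in, wtot_in)
    score = float((ls_out[valid].sum() + ls_in[valid].sum()) / (2.0 * V))
    return StabilityTerms(pstable_out, pstable_in, punif, ls_out, ls_in, score)


# --------------------------------------------------------------------------
# Seeding
# --------------------------------------------------------------------------

def _exclusion_sample_seeds(sym: sp.csr_matrix, nodes: np.ndarray, P: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Sample up to P seeds among ``nodes``, each disconnected from the seeds
    chosen so far and their neighbors; fall back to uniform sampling over the
    remaining nodes when the exclusion set covers everything."""
    nodes = np.asarray(nodes)
    available = np.ones(len(nodes), dtype=bool)
    pos = {v: i for i, v in enumerate(nodes)}
    seeds = []
    while len(seeds) < P and available.any():
        choice = int(rng.choice(nodes[available]))
        seeds.append(choice)
        available[pos[choice]] = False
        row = sym.indices[sym.indptr[choice]: sym.indptr[choice + 1]]
        for nb in row:
            if nb in pos:
                available[pos[nb]] = False
    if len(seeds) < P:
        remaining = nodes[~np.isin(nodes, seeds)]
        extra = rng.choice(remaining, size=min(P - len(seeds), len(remaining)),
                           replace=False)
        seeds.extend(int(v) for v in np.atleast_1d(extra))
    return np.asarray(seeds, dtype=np.int64)


def _assign_to_seeds(sym: sp.csr_matrix, nodes: np.ndarray, seeds: np.ndarray,
                     labels_out: np.ndarray, label_of_seed: np.ndarray) -> None:
    """Assign every node in ``nodes`` to the seeded group with the strongest
    total (balanced, symmetrized) edge weight, growing groups outward so
    nodes with no direct seed edge join via their neighborhood.  Ties and
    fully disconnected nodes resolve to the lowest seed label."""
    n = sym.shape[0]
    in_scope = np.zeros(n, dtype=bool)
    in_scope[nodes] = True
    for s, lab in zip(seeds, label_of_seed):
        labels_out[s] = lab

    sub = sym[nodes][:, nodes].tocsr()
    local_labels = labels_out[nodes].copy()
    unassigned = local_labels < 0
    # iterative frontier growth: connectivity to already-assigned members
    while unassigned.any():
        labs = np.unique(local_labels[~unassigned])
        ind = sp.csr_matrix(
            (np.ones((~unassigned).sum()),
             (np.flatnonzero(~unassigned),
              np.searchsorted(labs, local_labels[~unassigned]))),
            shape=(len(nodes), len(labs)),
        )
        conn = np.asarray((sub @ ind).todense())
        conn_un = conn[unassigned]
        best = np.argmax(conn_un, axis=1)
        strength = conn_un[np.arange(conn_un.shape[0]), best]
        reach = strength > 0
        if not reach.any():
            # disconnected leftovers: lowest seed label
            local_labels[unassigned] = labs[0]
            break
        idx_un = np.flatnonzero(unassigned)
        local_labels[idx_un[reach]] = labs[best[reach]]
        unassigned = local_labels < 0
    labels_out[nodes] = local_labels


def seed_partition(graph: WeightedCellGraph, P: int, rng: np.random.Generator) -> np.ndarray:
    """Seed P metacells by exclusion sampling and assign all nodes to them."""
    n = graph.n_nodes
    P = max(1, min(P, n))
    sym = graph.symmetric()
    nodes = np.arange(n)
    seeds = _exclusion_sample_seeds(sym, nodes, P, rng)
    mc = np.full(n, -1, dtype=np.int64)
    _assign_to_seeds(sym, nodes, seeds, mc, np.arange(len(seeds)))
    return compact_labels(mc)


# --------------------------------------------------------------------------
# Optimization driver
# --------------------------------------------------------------------------

def _init_state(graph: WeightedCellGraph, mc: np.ndarray):
    n = graph.n_nodes
    src, targ, w = _edge_arrays(graph)
    same = mc[src] == mc[targ]
    wtot_out = np.bincount(src, weights=w, minlength=n).astype(np.float64)
    win_out = np.bincount(src[same], weights=w[same], minlength=n).astype(np.float64)
    wtot_in = np.bincount(targ, weights=w, minlength=n).astype(np.float64)
    win_in = np.bincount(targ[same], weights=w[same], minlength=n).astype(np.float64)
    M = int(mc.max()) + 1
    sizes = np.bincount(mc, minlength=M).astype(np.int64)
    floored = ((win_out <= 0) | (wtot_out <= 0)).astype(np.int64) + \
              ((win_in <= 0) | (wtot_in <= 0)).astype(np.int64)
    nfloor = np.bincount(mc, weights=floored, minlength=M).astype(np.int64)
    return wtot_out, win_out, wtot_in, win_in, sizes, nfloor


def optimize_partition(
    graph: WeightedCellGraph,
    mc0: np.ndarray,
    rng: np.random.Generator,
    params: PartitionParams | None = None,
    lam_node: np.ndarray | None = None,
) -> np.ndarray:
    """Annealed single-node-move hill climbing on the stability score.

    At annealing level ``lam`` a move of node v is accepted when the score
    change plus ``lam * lam_node[v]`` times the change in v's own stability
    is positive; the final level is lam = 0 (pure score ascent).  The result
    never scores below the input (guarded by a fallback refinement of the
    input when annealing wanders off).
    """
    params = params or PartitionParams()
    mc0 = compact_labels(np.asarray(mc0, dtype=np.int64))
    if (mc0 < 0).any():
        raise ValueError("optimizer requires a full cover (no outliers)")
    if lam_node is None:
        lam_node = np.ones(graph.n_nodes, dtype=np.float64)
    out = graph.out_csr
    inc = graph.in_csr

    sym_csr = (graph.out_csr + graph.in_csr).tocsr()

    def neighborhood(nodes: np.ndarray) -> np.ndarray:
        cols = [nodes]
        for v in nodes:
            cols.append(sym_csr.indices[sym_csr.indptr[v]: sym_csr.indptr[v + 1]])
        return np.unique(np.concatenate(cols))

    def run_schedule(mc, schedule):
        moved = np.zeros(graph.n_nodes, dtype=np.bool_)
        for lam in schedule:
            wtot_out, win_out, wtot_in, win_in, sizes, nfloor = _init_state(graph, mc)
            active: np.ndarray | None = None  # None = sweep every node
            for _ in range(params.max_sweeps_per_level):
                pool = np.arange(graph.n_nodes) if active is None else active
                order = rng.permutation(pool)
                moved[:] = False
                moves = _sweep(
                    out.indptr, out.indices, out.data,
                    inc.indptr, inc.indices, inc.data,
                    mc, sizes, nfloor,
                    win_out, win_in, wtot_out, wtot_in,
                    float(lam), lam_node, params.log_stability_floor, order, moved,
                )
                if moves == 0:
                    if active is None:
                        break
                    active = None  # confirm convergence with a full sweep
                else:
                    # only nodes near a move can become profitable to move
                    active = neighborhood(np.flatnonzero(moved))
        return compact_labels(mc)

    mc = run_schedule(mc0.copy(), params.lambda_schedule)
    if compute_score(graph, mc, params).score < compute_score(graph, mc0, params).score:
        # annealing escaped to a worse basin; refine the input directly
        refined = run_schedule(mc0.copy(), (0.0,))
        if compute_score(graph, refined, params).score >= compute_score(graph, mc, params).score:
            mc = refined
    return mc


# --------------------------------------------------------------------------
# Size and connectivity control
# --------------------------------------------------------------------------

def _metacell_umis(mc: np.ndarray, u_capped: np.ndarray) -> np.ndarray:
    valid = mc >= 0
    if not valid.any():
        return np.zeros(0)
    return np.bincount(mc[valid], weights=u_capped[valid])


def _reseed_dissolved(graph: WeightedCellGraph, mc: np.ndarray,
                      dissolved: np.ndarray, P: int,
                      rng: np.random.Generator,
                      params: PartitionParams) -> np.ndarray:
    """Re-seed ``dissolved`` nodes into P fresh metacells and re-optimize,
    holding the annealing bonus at zero for every non-dissolved node."""
    mc = mc.copy()
    sym = graph.symmetric()
    P = max(1, min(P, len(dissolved)))
    seeds = _exclusion_sample_seeds(sym, dissolved, P, rng)
    base = int(mc[mc >= 0].max()) + 1 if (mc >= 0).any() else 0
    local = np.full(graph.n_nodes, -1, dtype=np.int64)
    _assign_to_seeds(sym, dissolved, seeds, local, base + np.arange(len(seeds)))
    mc[dissolved] = local[dissolved]
    lam_node = np.zeros(graph.n_nodes)
    lam_node[dissolved] = 1.0
    return optimize_partition(graph, mc, rng, params, lam_node=lam_node)


def enforce_max_size(
    graph: WeightedCellGraph,
    mc: np.ndarray,
    sizes: CellSizes,
    rng: np.random.Generator,
    params: PartitionParams | None = None,
) -> tuple[np.ndarray, int]:
    """Dissolve metacells whose capped UMI total reaches U_high; re-seed and
    re-optimize their cells.  Returns (partition, number dissolved)."""
    params = params or PartitionParams()
    mc = np.asarray(mc, dtype=np.int64)
    totals = _metacell_umis(mc, sizes.u_capped)
    over = np.flatnonzero(totals >= sizes.U_high)
    if over.size == 0:
        return mc, 0
    dissolved = np.flatnonzero(np.isin(mc, over))
    P = max(1, int(np.ceil(sizes.u_capped[dissolved].sum() / sizes.U_targ)))
    mc = mc.copy()
    mc[dissolved] = -1
    mc = compact_labels(mc)  # survivors keep dense labels; dissolved stay -1
    if (mc == OUTLIER).any() and (np.flatnonzero(mc == OUTLIER).size != dissolved.size):
        covered = np.flatnonzero((mc >= 0) | np.isin(np.arange(graph.n_nodes), dissolved))
        new_mc = _reseed_on_subset(graph, mc, covered, dissolved, P, rng, params)
    else:
        new_mc = _reseed_dissolved(graph, mc, dissolved, P, rng, params)
    return new_mc, int(over.size)


def _mincut_split(sub: sp.csr_matrix) -> tuple[float, np.ndarray, np.ndarray]:
    """Global min cut of a small symmetric weighted graph.

    Returns (cut weight, side1 indices, side2 indices).  Disconnected graphs
    short-circuit to a zero cut along the smallest component.
    """
    k = sub.shape[0]
    ncomp, comp = connected_components(sub, directed=False)
    if ncomp > 1:
        counts = np.bincount(comp)
        small = int(np.argmin(counts))
        side1 = np.flatnonzero(comp == small)
        side2 = np.flatnonzero(comp != small)
        return 0.0, side1, side2
    g = nx.Graph()
    g.add_nodes_from(range(k))
    coo = sp.triu(sub, k=1).tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        g.add_edge(int(i), int(j), weight=float(w))
    cut_value, (side1, side2) = nx.stoer_wagner(g)
    return float(cut_value), np.asarray(sorted(side1)), np.asarray(sorted(side2))


def enforce_connectivity(
    graph: WeightedCellGraph,
    mc: np.ndarray,
    rng: np.random.Generator,
    sizes: CellSizes,
    params: PartitionParams | None = None,
    force_coverage: bool = False,
) -> tuple[np.ndarray, bool]:
    """Min-cut test for every metacell.

    A metacell fails when the mean weight over node pairs crossing its global
    min cut (missing edges count as weight 0) is below
    ``mincut_weight_ratio`` times the mean weight over non-crossing pairs.
    A failing metacell with a small side (< ``mincut_min_split_cells``) has
    those cells disassociated (marked outliers; merged back instead under
    ``force_coverage``); otherwise the whole metacell is dissolved, re-seeded
    and re-optimized.  Returns (partition, whether anything changed).
    """
    params = params or PartitionParams()
    mc = np.asarray(mc, dtype=np.int64).copy()
    sym = graph.symmetric()
    changed = False
    dissolved_nodes: list[np.ndarray] = []
    n_dissolved_mcs = 0

    for m in np.unique(mc[mc >= 0]):
        members = np.flatnonzero(mc == m)
        # re-test after each disassociation until the metacell passes
        while members.size >= 2:
            k = members.size
            sub = sym[members][:, members].tocsr()
            cut_w, side1, side2 = _mincut_split(sub)
            n1, n2 = len(side1), len(side2)
            cut_pairs = n1 * n2
            noncut_pairs = k * (k - 1) // 2 - cut_pairs
            if noncut_pairs <= 0:
                break
            total_w = sp.triu(sub, k=1).sum()
            mean_cut = cut_w / cut_pairs
            mean_noncut = (total_w - cut_w) / noncut_pairs
            if mean_cut >= params.mincut_weight_ratio * mean_noncut:
                break
            changed = True
            small = side1 if n1 <= n2 else side2
            if len(small) < params.mincut_min_split_cells:
                if force_coverage:
                    dissolved_nodes.append(members[small])
                else:
                    mc[members[small]] = OUTLIER
                keep = np.ones(k, dtype=bool)
                keep[small] = False
                members = members[keep]
            else:
                dissolved_nodes.append(members)
                n_dissolved_mcs += 1
                break

    if dissolved_nodes:
        dissolved = np.concatenate(dissolved_nodes)
        P = max(1, int(np.ceil(sizes.u_capped[dissolved].sum() / sizes.U_targ)))
        mc[dissolved] = -1
        mc = compact_labels(mc)
        mc[dissolved] = -1
        # outliers (if any) must not enter the optimizer: restrict to cover
        if (mc == OUTLIER).any() and not force_coverage:
            covered = np.flatnonzero((mc >= 0) | np.isin(np.arange(len(mc)), dissolved))
            mc = _reseed_on_subset(graph, mc, covered, dissolved, P, rng, params)
        else:
            mc = _reseed_dissolved(graph, mc, dissolved, P, rng, params)
    return compact_labels_keep_outliers(mc), changed


def compact_labels_keep_outliers(mc: np.ndarray) -> np.ndarray:
    return compact_labels(mc)


def _reseed_on_subset(graph: WeightedCellGraph, mc: np.ndarray,
                      covered: np.ndarray, dissolved: np.ndarray, P: int,
                      rng: np.random.Generator,
                      params: PartitionParams) -> np.ndarray:
    """Re-seed dissolved nodes and re-optimize on the subgraph of covered
    nodes only (outliers stay outliers)."""
    sub_out = graph.out_csr[covered][:, covered].tocsr()
    sub_graph = WeightedCellGraph(out_csr=sub_out, K=graph.K,
                                  isolated=np.empty(0, np.int64))
    remap = -np.ones(graph.n_nodes, dtype=np.int64)
    remap[covered] = np.arange(len(covered))
    sub_mc = mc[covered].copy()
    sub_dissolved = remap[dissolved]
    sub_mc = _reseed_dissolved(sub_graph, sub_mc, sub_dissolved, P, rng, params)
    out = mc.copy()
    out[covered] = sub_mc
    return out


def _marker_metacells(counts: sp.csr_matrix, mc: np.ndarray,
                      marker_fold: float) -> np.ndarray:
    """Metacells with a gene whose depth-normalized pooled expression is at
    least ``marker_fold`` times the mean over all metacells."""
    valid = mc >= 0
    labels = np.unique(mc[valid])
    if labels.size == 0:
        return np.zeros(0, dtype=bool)
    ind = sp.csr_matrix(
        (np.ones(valid.sum()), (mc[valid], np.flatnonzero(valid))),
        shape=(labels.max() + 1, mc.size),
    )
    pooled = np.asarray((ind @ counts).todense(), dtype=np.float64)
    row_tot = pooled.sum(axis=1, keepdims=True)
    row_tot[row_tot == 0] = 1.0
    frac = pooled / row_tot
    grand = frac.mean(axis=0)
    with np.errstate(invalid="ignore"):
        marker = (frac >= marker_fold * grand) & (frac > 0) & (grand > 0)
    return marker.any(axis=1)


def enforce_min_size(
    graph: WeightedCellGraph,
    mc: np.ndarray,
    sizes: CellSizes,
    counts: sp.csr_matrix,
    rng: np.random.Generator,
    params: PartitionParams | None = None,
    force_coverage: bool = False,
) -> tuple[np.ndarray, list]:
    """Dissolve undersized metacells and redistribute their cells.

    A metacell is undersized when its capped UMI total is at most U_low
    (or 0.5*U_low if it carries a strong marker gene), or when it has fewer
    than ``min_metacell_cells`` members.  Dissolved cells are re-seeded with
    one seed fewer than the number of dissolved metacells; the loop stops
    when all metacells comply or a re-seeding round would create an
    oversized metacell (that round is rolled back).  Under
    ``force_coverage`` undersized metacells are merged into their
    best-connected neighbor metacell instead.
    """
    params = params or PartitionParams()
    mc = np.asarray(mc, dtype=np.int64).copy()
    warnings: list[str] = []
    sym = graph.symmetric()

    for _ in range(params.max_min_size_iterations):
        valid = mc >= 0
        if not valid.any():
            break
        totals = _metacell_umis(mc, sizes.u_capped)
        members = np.bincount(mc[valid], minlength=len(totals))
        marker = _marker_metacells(counts, mc, params.marker_fold)
        if marker.size < len(totals):
            marker = np.pad(marker, (0, len(totals) - marker.size))
        threshold = np.where(marker, 0.5 * sizes.U_low, sizes.U_low)
        small = ((totals <= threshold) | (members < params.min_metacell_cells)) & (members > 0)
        bad = np.flatnonzero(small)
        if bad.size == 0:
            break
        if len(np.unique(mc[valid])) <= 1:
            break  # nothing to redistribute into

        if force_coverage:
            for m in bad:
                nodes = np.flatnonzero(mc == m)
                conn = np.asarray(sym[nodes].sum(axis=0)).ravel()
                target_scores = np.bincount(
                    mc[valid], weights=conn[valid] * (mc[valid] != m), minlength=len(totals)
                )
                target_scores[m] = -1.0
                target_scores[members == 0] = -1.0
                if target_scores.max() > 0:
                    target = int(np.argmax(target_scores))
                else:
                    alive = np.flatnonzero((members > 0) & (np.arange(len(members)) != m))
                    target = int(alive[np.argmax(members[alive])])
                mc[nodes] = target
            mc = compact_labels(mc)
            continue

        dissolved = np.flatnonzero(np.isin(mc, bad))
        P = max(1, bad.size - 1)
        previous = mc.copy()
        mc[dissolved] = -1
        mc = compact_labels(mc)
        mc[dissolved] = -1
        if (mc == OUTLIER).any():
            covered = np.flatnonzero((mc >= 0) | np.isin(np.arange(len(mc)), dissolved))
            mc = _reseed_on_subset(graph, mc, covered, dissolved, P, rng, params)
        else:
            mc = _reseed_dissolved(graph, mc, dissolved, P, rng, params)
        new_totals = _metacell_umis(mc, sizes.u_capped)
        if (new_totals >= sizes.U_high).any():
            mc = previous
            warnings.append("min-size dissolution would create an oversized metacell")
            break
    else:
        warnings.append("min-size control did not converge")
    return compact_labels(mc), warnings


# --------------------------------------------------------------------------
# Full pile partition
# --------------------------------------------------------------------------

def partition_pile(
    graph: WeightedCellGraph,
    u: np.ndarray,
    counts: sp.csr_matrix,
    target_umis: int,
    rng: np.random.Generator,
    params: PartitionParams | None = None,
    force_coverage: bool = False,
    sizes: CellSizes | None = None,
) -> PartitionResult:
    """Seed, optimize, and apply all size/connectivity controls for one pile.

    ``u`` are the cells' raw UMI totals (used for sizing), ``counts`` the
    pile's (downsampled) matrix used only for the marker-gene exemption in
    min-size control.  ``sizes`` overrides the derived UMI bounds (used when
    partitions are sized in member cells instead of UMIs).
    """
    params = params or PartitionParams()
    n = graph.n_nodes
    warnings: list[str] = []

    if n < params.min_metacell_cells:
        return PartitionResult(np.zeros(n, dtype=np.int64),
                               ["pile smaller than one metacell"])

    if sizes is None:
        sizes = CellSizes.from_totals(u, target_umis, params.min_metacell_cells)
    P = max(1, int(np.ceil(sizes.u_capped.sum() / sizes.U_targ)))
    mc = seed_partition(graph, P, rng)
    mc = optimize_partition(graph, mc, rng, params)

    for _ in range(params.max_size_iterations):
        mc, n_over = enforce_max_size(graph, mc, sizes, rng, params)
        if n_over:
            continue
        mc, changed = enforce_connectivity(graph, mc, rng, sizes, params,
                                           force_coverage=force_coverage)
        if not changed:
            break
    else:
        warnings.append("max-size/connectivity loop did not converge")

    mc, min_warnings = enforce_min_size(graph, mc, sizes, counts, rng, params,
                                        force_coverage=force_coverage)
    warnings.extend(min_warnings)

    if force_coverage and (mc == OUTLIER).any():  # safety net: full cover promised
        mc = _merge_outliers_by_connectivity(graph, mc)
    return PartitionResult(compact_labels(mc), warnings)


def _merge_outliers_by_connectivity(graph: WeightedCellGraph, mc: np.ndarray) -> np.ndarray:
    """Attach outlier nodes to their best-connected metacell (fallback: 0)."""
    mc = mc.copy()
    sym = graph.symmetric()
    pending = np.flatnonzero(mc == OUTLIER)
    for _ in range(len(pending) + 1):
        if pending.size == 0:
            break
        progressed = False
        for v in pending:
            row = sym.indices[sym.indptr[v]: sym.indptr[v + 1]]
            wts = sym.data[sym.indptr[v]: sym.indptr[v + 1]]
            labs = mc[row]
            ok = labs >= 0
            if ok.any():
                scores = np.bincount(labs[ok], weights=wts[ok])
                mc[v] = int(np.argmax(scores))
                progressed = True
        pending = np.flatnonzero(mc == OUTLIER)
        if not progressed:
            mc[pending] = 0
            break
    return mc
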
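"""Ground-truthed synthetic UMI matrices.

The generator embodies the idealized model behind metacells: each cell is a
multinomial sample from the expression profile of its (discrete) state, at a
cell-specific sequencing depth.  On top of that baseline it can plant

* a *rare type*: a tiny group of cells whose profile expresses a dedicated
  gene module absent from the background, and
* *deviant cells*: ordinary cells with one gene's count inflated by a known
  fold (depth-preserving), mimicking stress/doublet-like artifacts.

Everything is deterministic given the seed, and the planted truth is
recorded so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data_io import UMIMatrix

_CHUNK_CELLS = 20_000  # bound on the dense block materialized at a time


@dataclass
class DepthModel:
    """Log-normal per-cell UMI depths, truncated to a plausible droplet range."""

    median: float = 2000.0
    sigma: float = 0.4
    low: int = 500
    high: int = 20_000

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        depths = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)
        return np.clip(np.round(depths), self.low, self.high).astype(np.int64)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic matrix."""

    state_labels: np.ndarray                 # per-cell state index
    state_profiles: np.ndarray               # n_states x n_genes, rows sum to 1
    rare_module_genes: list = field(default_factory=list)   # gene indices
    rare_cells: list = field(default_factory=list)          # cell indices
    deviant_events: list = field(default_factory=list)      # (cell, gene, fold)
    params: dict = field(default_factory=dict)

    RARE_STATE = -2  # label assigned to planted rare cells

    def to_json(self, path) -> None:
        payload = {
            "state_labels": np.asarray(self.state_labels).tolist(),
            "state_profiles": np.asarray(self.state_profiles).tolist(),
            "rare_module_genes": [int(g) for g in self.rare_module_genes],
            "rare_cells": [int(c) for c in self.rare_cells],
            "deviant_events": [[int(c), int(g), float(f)] for c, g, f in self.deviant_events],
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            state_labels=np.asarray(payload["state_labels"], dtype=np.int64),
            state_profiles=np.asarray(payload["state_profiles"], dtype=np.float64),
            rare_module_genes=payload["rare_module_genes"],
            rare_cells=payload["rare_cells"],
            deviant_events=[tuple(e) for e in payload["deviant_events"]],
            params=payload["params"],
        )


def _multinomial_rows(depths: np.ndarray, pvals: np.ndarray,
                      rng: np.random.Generator) -> sp.csr_matrix:
    """Sparse multinomial draws, one row per depth, all sharing ``pvals``."""
    blocks = []
    for lo in range(0, len(depths), _CHUNK_CELLS):
        chunk = rng.multinomial(depths[lo:lo + _CHUNK_CELLS], pvals)
        blocks.append(sp.csr_matrix(chunk.astype(np.int32)))
    return sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, len(pvals)))


def _state_profiles(n_states: int, n_genes: int, separation: float,
                    markers_per_state: int, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Shared heavy-tailed backbone plus disjoint elevated marker blocks."""
    backbone = rng.gamma(shape=0.5, scale=1.0, size=n_genes)
    backbone = np.maximum(backbone, 1e-9)
    backbone /= backbone.sum()

    total_markers = n_states * markers_per_state
    if total_markers > n_genes // 2:
        raise ValueError("too many marker genes for the number of genes")
    # markers drawn from mid-expression genes so feature selection stays nontrivial
    order = np.argsort(backbone)
    mid = order[n_genes // 4: n_genes // 4 + max(total_markers, n_genes // 2)]
    markers = rng.choice(mid, size=total_markers, replace=False)
    marker_sets = markers.reshape(n_states, markers_per_state)

    profiles = np.tile(backbone, (n_states, 1))
    for s in range(n_states):
        profiles[s, marker_sets[s]] *= separation
        profiles[s] /= profiles[s].sum()
    return profiles, marker_sets


def generate_states(
    n_states: int,
    n_genes: int,
    n_cells: int,
    seed: int,
    separation: float = 4.0,
    markers_per_state: int | None = None,
    depth: DepthModel | None = None,
) -> tuple[UMIMatrix, GroundTruth]:
    """Multinomial cells from ``n_states`` discrete expression states.

    ``separation`` is the fold elevation of each state's marker genes over
    the shared backbone; with the default marker count the markers carry
    roughly 10% of a state's probability mass at separation 4.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    depth = depth or DepthModel()
    if markers_per_state is None:
        markers_per_state = max(5, int(round(0.03 * n_genes)))

    if separation <= 0:
        raise ValueError("separation must be positive")
    profiles, marker_sets = _state_profiles(n_states, n_genes, separation,
                                            markers_per_state, rng)
    labels = rng.integers(0, n_states, size=n_cells)
    depths = depth.sample(n_cells, rng)

    # draw per-state blocks; rows are stored grouped by state (cells are
    # exchangeable, so only the labels array need match the row order)
    labels = np.sort(labels, kind="stable")
    blocks = []
    for s in range(n_states):
        idx = np.flatnonzero(labels == s)
        blocks.append(_multinomial_rows(depths[idx], profiles[s], rng))
    X = sp.vstack(blocks, format="csr") if blocks else sp.csr_matrix((0, n_genes))

    cell_ids = np.array([f"cell{i:07d}" for i in range(n_cells)], dtype=object)
    gene_ids = np.array([f"gene{g:05d}" for g in range(n_genes)], dtype=object)
    truth = GroundTruth(
        state_labels=labels,
        state_profiles=profiles,
        params={
            "n_states": n_states, "n_genes": n_genes, "n_cells": n_cells,
            "separation": separation, "markers_per_state": markers_per_state,
            "seed": seed, "marker_sets": marker_sets.tolist(),
            "depth": {"median": depth.median, "sigma": depth.sigma,
                      "low": depth.low, "high": depth.high},
        },
    )
    return UMIMatrix(X, cell_ids, gene_ids), truth


def plant_rare_type(
    m: UMIMatrix,
    truth: GroundTruth,
    frequency: float,
    seed: int,
    module_size: int = 5,
    enrichment: float = 50.0,
) -> tuple[UMIMatrix, GroundTruth]:
    """Rewrite ``round(frequency * n_cells)`` cells from a rare-type profile.

    The rare profile dedicates ``module_size`` genes, chosen from the genes
    with the smallest backbone probability (so the background essentially
    never expresses them), and raises each to ``enrichment`` times the mean
    per-gene probability (1/n_genes).  At enrichment 50 and median depth
    2000 each module gene contributes ~50 UMIs per rare cell.
    """
    n_planted = int(round(frequency * m.n_cells))
    if n_planted == 0:
        return m, truth
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))

    backbone = truth.state_profiles.mean(axis=0)
    taken = set(truth.rare_module_genes)
    for ms in truth.params.get("marker_sets", []):
        taken.update(ms)
    candidates = [g for g in np.argsort(backbone) if g not in taken]
    module_genes = np.asarray(candidates[:module_size], dtype=np.int64)

    profile = backbone.copy()
    profile[module_genes] = enrichment / m.n_genes
    profile /= profile.sum()

    eligible = np.flatnonzero(~np.isin(np.arange(m.n_cells), truth.rare_cells))
    cells = np.sort(rng.choice(eligible, size=n_planted, replace=False))
    depths = m.cell_totals()[cells]

    block = _multinomial_rows(depths, profile, rng)
    X = _replace_rows(m.X, cells, block)
    labels = truth.state_labels.copy()
    labels[cells] = GroundTruth.RARE_STATE

    new_truth = GroundTruth(
        state_labels=labels,
        state_profiles=truth.state_profiles,
        rare_module_genes=list(truth.rare_module_genes) + module_genes.tolist(),
        rare_cells=list(truth.rare_cells) + cells.tolist(),
        deviant_events=list(truth.deviant_events),
        params={**truth.params,
                "rare": {"frequency": frequency, "module_size": module_size,
                         "enrichment": enrichment, "seed": seed}},
    )
    return UMIMatrix(X, m.cell_ids, m.gene_ids), new_truth


def _replace_rows(X: sp.csr_matrix, rows: np.ndarray,
                  block: sp.csr_matrix) -> sp.csr_matrix:
    """Copy of ``X`` with ``rows`` replaced by the rows of ``block``.

    Splices the CSR arrays directly (one extra copy of data/indices) so the
    peak memory stays ~2x the matrix, not 4x.
    """
    X = X.tocsr()
    block = block.tocsr()
    rows = np.asarray(rows, dtype=np.int64)  # assumed sorted ascending
    n = X.shape[0]
    lengths = np.diff(X.indptr).astype(np.int64)
    lengths[rows] = np.diff(block.indptr)
    new_indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lengths, out=new_indptr[1:])
    new_data = np.empty(int(new_indptr[-1]), dtype=X.data.dtype)
    new_indices = np.empty(int(new_indptr[-1]), dtype=X.indices.dtype)

    # copy unchanged stretches between replaced rows, then splice new rows
    boundaries = np.concatenate([[-1], rows, [n]])
    for i in range(len(boundaries) - 1):
        lo_row, hi_row = boundaries[i] + 1, boundaries[i + 1]
        if lo_row < hi_row:
            src = slice(X.indptr[lo_row], X.indptr[hi_row])
            dst = slice(new_indptr[lo_row], new_indptr[hi_row])
            new_data[dst] = X.data[src]
            new_indices[dst] = X.indices[src]
        if hi_row < n and i < len(rows) + 1 and hi_row in rows:
            k = int(np.searchsorted(rows, hi_row))
            src = slice(block.indptr[k], block.indptr[k + 1])
            dst = slice(new_indptr[hi_row], new_indptr[hi_row + 1])
            new_data[dst] = block.data[src]
            new_indices[dst] = block.indices[src]
    return sp.csr_matrix((new_data, new_indices, new_indptr), shape=X.shape)


def plant_deviant_cells(
    m: UMIMatrix,
    truth: GroundTruth,
    n_cells: int,
    fold: float,
    seed: int,
) -> tuple[UMIMatrix, GroundTruth]:
    """Inflate one gene ``fold``-fold in each of ``n_cells`` cells.

    The gene is raised to ``fold`` times its *expected* count under the
    cell's state profile (so the inflation is unambiguous relative to the
    population, not to one noisy draw), choosing a gene whose expectation is
    at least 3 UMIs — below that, pseudo-count regularization of fold
    factors makes the nominal fold unattainable.  The cell's depth is preserved: after inflation the
    whole row is subsampled (without replacement) back to the original
    total.  ``fold`` of 1 (or zero cells) is the identity.
    """
    if n_cells == 0 or fold == 1.0:
        return m, truth
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    eligible = np.flatnonzero(~np.isin(np.arange(m.n_cells), truth.rare_cells))
    chosen = np.sort(rng.choice(eligible, size=n_cells, replace=False))

    csr = m.X.tocsr()
    new_rows, events = [], []
    for cell in chosen:
        lo, hi = csr.indptr[cell], csr.indptr[cell + 1]
        cols = csr.indices[lo:hi].astype(np.int64)
        vals = csr.data[lo:hi].astype(np.int64).copy()
        depth = int(vals.sum())
        profile = truth.state_profiles[truth.state_labels[cell]]
        expected = profile[cols] * depth
        candidates = np.flatnonzero(expected >= 3)
        if candidates.size == 0:
            candidates = np.array([int(np.argmax(expected))])
        k = int(rng.choice(candidates))
        vals[k] = max(vals[k], int(round(expected[k] * fold)))
        # subsample back to the original depth
        new_vals = rng.multivariate_hypergeometric(vals, depth)
        row = sp.csr_matrix((new_vals, (np.zeros_like(cols), cols)),
                            shape=(1, m.n_genes))
        row.eliminate_zeros()
        new_rows.append(row)
        events.append((int(cell), int(cols[k]), float(fold)))
    X = _replace_rows(csr, chosen, sp.vstack(new_rows, format="csr"))

    new_truth = GroundTruth(
        state_labels=truth.state_labels,
        state_profiles=truth.state_profiles,
        rare_module_genes=list(truth.rare_module_genes),
        rare_cells=list(truth.rare_cells),
        deviant_events=list(truth.deviant_events) + events,
        params={**truth.params,
                "deviants": {"n_cells": n_cells, "fold": fold, "seed": seed}},
    )
    return UMIMatrix(X, m.cell_ids, m.gene_ids), new_truth
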
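"""The divide-and-conquer driver.

Direct graph partitioning is quadratic in the number of cells, so large
matrices are processed in *piles* of manageable size:

1. **Preliminary phase** — cells go to random piles; each pile runs the
   basic algorithm (features -> graph -> partition -> deviant removal).
   Outliers from all piles are pooled and re-piled until a single outlier
   pile remains, which is partitioned with 100% coverage.  The result is a
   complete but low-quality partition.
2. **Metagroup phase** — preliminary metacells become single observations
   (pooled UMI profiles) and the same machinery groups them into
   *metagroups* of 5000-12,500 member cells, with full coverage.
3. **Final phase** — each metagroup's cells form one pile; the basic
   algorithm runs once more, outliers get exactly one regrouping round, and
   whatever remains is a *final outlier*.

A rare-gene-module pre-process runs first on large inputs: cells of each
detected module form a dedicated pile whose metacells pass straight to the
output, so states present at ~1e-4 frequency are not lost to random piling.
Per-pile seeds derive from the master seed and the (phase, level, pile)
key, so piles can be processed in any order with identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _seeds
from .cell_graph import FeatureSelectionError, build_balanced_knn, choose_K, select_features
from .config import PipelineConfig
from .data_io import CellSizes, UMIMatrix, choose_downsample_target, downsample_cells
from .deviants import iterate_deviant_removal
from .partition import OUTLIER, compact_labels, partition_pile

FINAL_OUTLIER = -1


# --------------------------------------------------------------------------
# Pile sizing and random piling
# --------------------------------------------------------------------------

def choose_pile_size(n_cells: int, target_umis: int, median_cell_umis: float,
                     cfg: PipelineConfig | None = None) -> int:
    """Cells per random pile so a pile yields ~``target_metacells_per_pile``
    metacells, clamped to the configured bounds."""
    cfg = cfg or PipelineConfig()
    p = cfg.piles
    if median_cell_umis <= 0:
        return p.min_pile_cells
    raw = p.target_metacells_per_pile * target_umis / median_cell_umis
    return int(np.clip(raw, p.min_pile_cells, p.max_pile_cells))


def random_piles(n: int, pile_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded shuffle, then near-equal splits of at most ``pile_size`` cells."""
    order = rng.permutation(n)
    n_piles = max(1, int(np.ceil(n / pile_size)))
    return [np.sort(chunk) for chunk in np.array_split(order, n_piles)]


# --------------------------------------------------------------------------
# The basic (single-pile) algorithm
# --------------------------------------------------------------------------

def basic_metacells(
    m: UMIMatrix,
    cfg: PipelineConfig,
    rng: np.random.Generator,
    force_coverage: bool = False,
    sizes: CellSizes | None = None,
    u: np.ndarray | None = None,
) -> tuple[np.ndarray, list]:
    """Features -> balanced K-nn graph -> partition (-> deviant removal).

    Returns a per-cell metacell assignment (-1 = outlier) and warnings.
    With ``force_coverage`` deviant removal is skipped and no cell is left
    unassigned.  ``u``/``sizes`` override the per-observation size totals
    (used by the metagroup phase, where observations are pooled profiles
    weighted by member-cell counts).
    """
    n = m.n_cells
    if u is None:
        u = m.cell_totals().astype(np.float64)
    if n < cfg.partition.min_metacell_cells:
        if force_coverage:
            return np.zeros(n, dtype=np.int64), ["pile smaller than one metacell"]
        return np.full(n, OUTLIER, dtype=np.int64), ["pile smaller than one metacell"]

    target = sizes.U_targ if sizes is not None else cfg.target_umis
    # the downsampling clip is always in UMIs, even when partition sizing is
    # in member cells (metagroup phase)
    ds_target = choose_downsample_target(m.cell_totals(),
                                         max(target, cfg.target_umis),
                                         cfg.downsample_min_umis)
    ds = downsample_cells(m, ds_target, int(rng.integers(2**31)))

    try:
        selection = select_features(ds, frozenset(cfg.forbidden_genes), cfg.features)
    except FeatureSelectionError:
        if force_coverage:
            return np.zeros(n, dtype=np.int64), ["no feature genes; single metacell"]
        return np.full(n, OUTLIER, dtype=np.int64), ["no feature genes; pile unpartitionable"]

    K = choose_K(u, target)
    graph = build_balanced_knn(ds, selection.feature_genes, K, cfg.graph)
    result = partition_pile(graph, u, ds.X, target, rng, cfg.partition,
                            force_coverage=force_coverage, sizes=sizes)
    mc = result.mc
    warnings = list(result.warnings)

    if not force_coverage:
        mc, _report = iterate_deviant_removal(ds.X, mc, u, target,
                                              cfg.deviants, cfg.partition)
    return mc, warnings


# --------------------------------------------------------------------------
# Solution container
# --------------------------------------------------------------------------

@dataclass
class MetacellSolution:
    """Final cell -> metacell map with pooled profiles and provenance."""

    cell_metacell: np.ndarray          # per cell: metacell id or -1 (final outlier)
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    pooled: sp.csr_matrix              # n_metacells x genes, exact count sums
    provenance: np.ndarray             # per metacell: "rare" | "main"
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    @property
    def n_metacells(self) -> int:
        return self.pooled.shape[0]

    @property
    def n_outliers(self) -> int:
        return int((self.cell_metacell == FINAL_OUTLIER).sum())

    def members(self, metacell: int) -> np.ndarray:
        return np.flatnonzero(self.cell_metacell == metacell)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "metacell_id": self.cell_metacell})

    def pooled_matrix(self) -> UMIMatrix:
        names = np.array([f"MC{i}" for i in range(self.n_metacells)], dtype=object)
        return UMIMatrix(self.pooled.copy(), names, self.gene_ids)

    def save(self, directory) -> None:
        from pathlib import Path

        from .data_io import save_umi_matrix

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "cell_metacell.tsv", sep="\t", index=False)
        pooled = self.pooled_matrix()
        save_umi_matrix(pooled, directory / "metacells_mtx", fmt="mtx_dir")
        save_umi_matrix(pooled, directory / "metacells.h5ad", fmt="h5")
        with open(directory / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _assemble_solution(m: UMIMatrix, mc: np.ndarray, provenance_of: dict,
                       warnings: list, manifest: dict) -> MetacellSolution:
    mc = compact_labels(mc)
    valid = mc >= 0
    M = int(mc[valid].max()) + 1 if valid.any() else 0
    if M:
        ind = sp.csr_matrix(
            (np.ones(valid.sum()), (mc[valid], np.flatnonzero(valid))),
            shape=(M, m.n_cells),
        )
        pooled = (ind @ m.X).astype(np.int64).tocsr()
    else:
        pooled = sp.csr_matrix((0, m.n_genes), dtype=np.int64)
    provenance = np.array([provenance_of.get(i, "main") for i in range(M)], dtype=object)
    return MetacellSolution(
        cell_metacell=mc, cell_ids=m.cell_ids, gene_ids=m.gene_ids,
        pooled=pooled, provenance=provenance, warnings=warnings, manifest=manifest,
    )


# --------------------------------------------------------------------------
# Phases
# --------------------------------------------------------------------------

def _run_pile_set(m: UMIMatrix, piles: list[np.ndarray], cfg: PipelineConfig,
                  master_seed: int, phase: int, level: int,
                  mc_out: np.ndarray, next_label: int,
                  force_coverage: bool = False) -> tuple[int, list]:
    """Run the basic algorithm on each pile, writing global labels into
    ``mc_out``; returns (next free label, warnings)."""
    warnings = []
    for pid, pile in enumerate(piles):
        rng = _seeds.derive_rng(master_seed, phase, level, pid)
        sub = m.subset_cells(pile)
        mc, w = basic_metacells(sub, cfg, rng, force_coverage=force_coverage)
        warnings.extend(w)
        assigned = mc >= 0
        mc_out[pile[assigned]] = mc[assigned] + next_label
        mc_out[pile[~assigned]] = OUTLIER
        if assigned.any():
            next_label += int(mc[assigned].max()) + 1
    return next_label, warnings


def preliminary_phase(m: UMIMatrix, cfg: PipelineConfig, seed: int,
                      pile_size: int) -> tuple[np.ndarray, list]:
    """Random piling with outlier re-piling until full coverage."""
    n = m.n_cells
    mc = np.full(n, OUTLIER, dtype=np.int64)
    warnings: list = []
    current = np.arange(n)
    next_label = 0
    level = 0
    while current.size > pile_size:
        rng = _seeds.derive_rng(seed, _seeds.PHASE_PRELIMINARY, level)
        piles = [current[p] for p in random_piles(current.size, pile_size, rng)]
        next_label, w = _run_pile_set(m, piles, cfg, seed,
                                      _seeds.PHASE_PRELIMINARY, level, mc, next_label)
        warnings.extend(w)
        current = np.flatnonzero(mc == OUTLIER)
        level += 1
        if level > 64:
            warnings.append("preliminary outlier recursion did not shrink")
            break
    if current.size:
        # the final single outlier pile: forced 100% coverage
        next_label, w = _run_pile_set(m, [current], cfg, seed,
                                      _seeds.PHASE_PRELIMINARY, level, mc,
                                      next_label, force_coverage=True)
        warnings.extend(w)
    return compact_labels(mc), warnings


def _group_observations(obs: UMIMatrix, weights: np.ndarray, cfg: PipelineConfig,
                        seed: int, level: int = 0) -> np.ndarray:
    """Recursively group observations (pooled profiles weighted by member-cell
    counts) into partitions of ``metagroup_min_cells``..``metagroup_max_cells``
    member cells, with forced coverage."""
    n_obs = obs.n_cells
    lo, hi = cfg.piles.metagroup_min_cells, cfg.piles.metagroup_max_cells
    target = int((lo + hi) / 2)
    sizes = CellSizes(u=weights.astype(np.float64),
                      u_capped=np.minimum(weights, 2 * np.median(weights)).astype(np.float64),
                      U_targ=target, U_low=float(lo), U_high=float(hi))

    if n_obs <= cfg.piles.max_pile_cells:
        rng = _seeds.derive_rng(seed, _seeds.PHASE_METAGROUP, level, 0)
        mc, _ = basic_metacells(obs, cfg, rng, force_coverage=True,
                                sizes=sizes, u=weights.astype(np.float64))
        return compact_labels(mc)

    # more observations than one pile: pile them, group within piles, then
    # recurse on the pooled group profiles
    rng = _seeds.derive_rng(seed, _seeds.PHASE_METAGROUP, level)
    piles = random_piles(n_obs, cfg.piles.max_pile_cells, rng)
    labels = np.full(n_obs, -1, dtype=np.int64)
    next_label = 0
    for pid, pile in enumerate(piles):
        prng = _seeds.derive_rng(seed, _seeds.PHASE_METAGROUP, level, pid + 1)
        sub = obs.subset_cells(pile)
        mc, _ = basic_metacells(sub, cfg, prng, force_coverage=True,
                                sizes=sizes, u=weights[pile].astype(np.float64))
        labels[pile] = mc + next_label
        next_label += int(mc.max()) + 1
    labels = compact_labels(labels)
    M = int(labels.max()) + 1
    ind = sp.csr_matrix((np.ones(n_obs), (labels, np.arange(n_obs))), shape=(M, n_obs))
    pooled = (ind @ obs.X).astype(np.int64).tocsr()
    group_weights = np.bincount(labels, weights=weights, minlength=M)
    group_obs = UMIMatrix(pooled,
                          np.array([f"grp{level}_{i}" for i in range(M)], dtype=object),
                          obs.gene_ids)
    upper = _group_observations(group_obs, group_weights, cfg, seed, level + 1)
    return compact_labels(upper[labels])


def metagroup_phase(m: UMIMatrix, prelim_mc: np.ndarray, cfg: PipelineConfig,
                    seed: int) -> np.ndarray:
    """Group preliminary metacells (as pooled observations) into metagroups."""
    M = int(prelim_mc.max()) + 1
    ind = sp.csr_matrix(
        (np.ones(m.n_cells), (prelim_mc, np.arange(m.n_cells))), shape=(M, m.n_cells)
    )
    pooled = (ind @ m.X).astype(np.int64).tocsr()
    weights = np.bincount(prelim_mc, minlength=M).astype(np.float64)
    obs = UMIMatrix(pooled,
                    np.array([f"prelim{i}" for i in range(M)], dtype=object),
                    m.gene_ids)
    return _group_observations(obs, weights, cfg, seed)


def final_phase(m: UMIMatrix, metagroup_of_cell: np.ndarray, cfg: PipelineConfig,
                seed: int, pile_size: int) -> tuple[np.ndarray, list]:
    """Partition each metagroup pile; outliers get exactly one more round."""
    n = m.n_cells
    mc = np.full(n, OUTLIER, dtype=np.int64)
    piles = [np.flatnonzero(metagroup_of_cell == g)
             for g in np.unique(metagroup_of_cell)]
    next_label, warnings = _run_pile_set(m, piles, cfg, seed,
                                         _seeds.PHASE_FINAL, 0, mc, 0)

    outliers = np.flatnonzero(mc == OUTLIER)
    if outliers.size:
        rng = _seeds.derive_rng(seed, _seeds.PHASE_OUTLIER, 0)
        opiles = [outliers[p] for p in random_piles(outliers.size, pile_size, rng)]
        next_label, w = _run_pile_set(m, opiles, cfg, seed,
                                      _seeds.PHASE_OUTLIER, 1, mc, next_label)
        warnings.extend(w)
    return mc, warnings  # cells still at -1 are final outliers


# --------------------------------------------------------------------------
# Top-level entry points
# --------------------------------------------------------------------------

def compute_metacells_direct(m: UMIMatrix, cfg: PipelineConfig | None = None,
                             seed: int = 0) -> MetacellSolution:
    """The basic algorithm on the whole matrix as one pile (no divide and
    conquer), with one outlier regrouping round — practical only for inputs
    that fit a single pile."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    if m.n_cells == 0:
        raise ValueError("empty matrix")
    mc = np.full(m.n_cells, OUTLIER, dtype=np.int64)
    next_label, warnings = _run_pile_set(m, [np.arange(m.n_cells)], cfg, seed,
                                         _seeds.PHASE_SINGLE, 0, mc, 0)
    outliers = np.flatnonzero(mc == OUTLIER)
    if outliers.size:
        next_label, w = _run_pile_set(m, [outliers], cfg, seed,
                                      _seeds.PHASE_SINGLE, 1, mc, next_label)
        warnings.extend(w)
    manifest = {"mode": "single_pile", "seed": seed, "n_cells": m.n_cells,
                "config": cfg.to_dict()}
    return _assemble_solution(m, mc, {}, warnings, manifest)


def compute_metacells(m: UMIMatrix, cfg: PipelineConfig | None = None,
                      seed: int = 0) -> MetacellSolution:
    """Full pipeline: rare-module pre-process plus three-phase divide and
    conquer (or the direct algorithm when everything fits one pile)."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    if m.n_cells == 0:
        raise ValueError("empty matrix")

    median_umis = float(np.median(m.cell_totals()))
    pile_size = choose_pile_size(m.n_cells, cfg.target_umis, median_umis, cfg)
    if m.n_cells <= pile_size:
        # single pile: the rare-module pre-process exists to rescue states
        # lost to random piling, which cannot happen here
        return compute_metacells_direct(m, cfg, seed)

    mc = np.full(m.n_cells, OUTLIER, dtype=np.int64)
    provenance_of: dict[int, str] = {}
    warnings: list = []
    next_label = 0
    manifest = {"mode": "divide_and_conquer", "seed": seed,
                "n_cells": m.n_cells, "pile_size": pile_size,
                "config": cfg.to_dict(), "phases": {}}

    main_cells = np.arange(m.n_cells)
    if cfg.rare.enabled:
        from .rare_modules import detect_rare_modules

        modules, assignment = detect_rare_modules(m, cfg.rare, pile_size)
        manifest["phases"]["rare_modules"] = {
            "n_modules": len(modules),
            "n_cells": int((assignment >= 0).sum()),
        }
        for midx in range(len(modules)):
            pile = np.flatnonzero(assignment == midx)
            rng = _seeds.derive_rng(seed, _seeds.PHASE_RARE, midx)
            sub = m.subset_cells(pile)
            sub_mc, w = basic_metacells(sub, cfg, rng)
            warnings.extend(w)
            assigned = sub_mc >= 0
            mc[pile[assigned]] = sub_mc[assigned] + next_label
            if assigned.any():
                for lab in range(int(sub_mc[assigned].max()) + 1):
                    provenance_of[next_label + lab] = "rare"
                next_label += int(sub_mc[assigned].max()) + 1
        main_cells = np.flatnonzero(mc == OUTLIER)  # incl. rare-pile outliers

    sub = m.subset_cells(main_cells)
    if sub.n_cells <= pile_size:
        part = compute_metacells_direct(sub, cfg, seed)
        sub_mc = part.cell_metacell
        warnings.extend(part.warnings)
        manifest["phases"]["main"] = {"mode": "single_pile"}
    else:
        prelim, w1 = preliminary_phase(sub, cfg, seed, pile_size)
        groups_of_mc = metagroup_phase(sub, prelim, cfg, seed)
        sub_mc, w2 = final_phase(sub, groups_of_mc[prelim], cfg, seed, pile_size)
        warnings.extend(w1)
        warnings.extend(w2)
        manifest["phases"]["main"] = {
            "mode": "three_phase",
            "n_preliminary_metacells": int(prelim.max()) + 1,
            "n_metagroups": int(groups_of_mc.max()) + 1,
        }
    assigned = sub_mc >= 0
    mc[main_cells[assigned]] = sub_mc[assigned] + next_label

    solution = _assemble_solution(m, mc, provenance_of, warnings, manifest)
    solution.manifest["n_metacells"] = solution.n_metacells
    solution.manifest["n_final_outliers"] = solution.n_outliers
    return solution
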
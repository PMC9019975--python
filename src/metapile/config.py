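"""Tunable parameters for the metacell pipeline.

All knobs are collected in small frozen-ish dataclasses so a whole run is
reproducible from one :class:`PipelineConfig` plus one integer seed.  The
defaults target typical droplet scRNA-seq (median cell depth of a few
thousand UMIs); tests and small examples override the size-related fields.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


@dataclass
class RareModuleParams:
    """Thresholds for the rare-gene-module pre-process.

    A *rare gene* is one seen in at most ``max_cell_fraction`` of cells but
    with at least ``min_max_umis`` UMIs in some single cell.  Candidate
    modules are subtrees of a Ward dendrogram over the second-order gene
    correlation matrix with at least ``min_module_genes`` genes and mean
    off-diagonal correlation at least ``min_mean_r2``.
    """

    max_cell_fraction: float = 1e-3
    min_max_umis: int = 7
    min_module_genes: int = 4
    min_mean_r2: float = 0.1
    expansion_fold: float = 128.0
    expansion_cell_growth_cap: float = 4.0
    min_module_umis_per_cell: int = 4
    min_module_cells: int = 12
    pile_target_cells: int = 48
    enabled: bool = True

    def validate(self) -> None:
        if not (0 < self.max_cell_fraction < 1):
            raise ValueError("max_cell_fraction must be in (0, 1)")
        for name in ("min_max_umis", "min_module_genes", "min_module_umis_per_cell",
                     "min_module_cells", "pile_target_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.expansion_fold <= 1 or self.expansion_cell_growth_cap <= 1:
            raise ValueError("expansion parameters must exceed 1")


@dataclass
class FeatureParams:
    """Per-pile feature-gene election thresholds (applied after downsampling)."""

    min_gene_total_umis: int = 50        # total UMIs of the gene in the pile
    min_umis_per_cell: int = 4           # at least this many UMIs ...
    min_expressing_cells: int = 3        # ... in at least this many cells
    normalized_variance_gap: float = 0.1  # var/mean excess over local median
    expression_window: int = 100         # genes of most similar mean expression


@dataclass
class GraphParams:
    """Balanced K-nn graph construction."""

    balance_prune_factor: float = math.sqrt(10.0)  # keep ~sqrt(10)*K candidates/cell
    max_incoming_factor: int = 3                   # in-degree cap = 3K
    # K itself is derived per pile: ceil(target_umis / median cell depth).


@dataclass
class PartitionParams:
    """Two-sided stability score optimization and size/connectivity control."""

    min_metacell_cells: int = 12
    lambda_schedule: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5, 0.25, 0.0)
    log_stability_floor: float = -10.0   # replaces -inf for one-sided nodes
    mincut_weight_ratio: float = 0.1     # mean cut weight < ratio * mean kept weight
    mincut_min_split_cells: int = 7      # smaller sides below this are disassociated
    marker_fold: float = 8.0             # gene 8-fold over grand mean marks a metacell
    max_size_iterations: int = 20
    max_min_size_iterations: int = 20
    max_sweeps_per_level: int = 100


@dataclass
class DeviantParams:
    """Adaptive deviant (outlier) cell detection."""

    fold_baseline: float = 8.0           # minimal fold factor of a deviant gene
    max_deviant_gene_fraction: float = 0.03
    cells_per_gene_baseline: int = 1     # max cells removed per single gene
    max_deviant_cell_fraction: float = 0.25
    enabled: bool = True

    def validate(self) -> None:
        if self.fold_baseline <= 1:
            raise ValueError("fold_baseline must exceed 1")
        for name in ("max_deviant_gene_fraction", "max_deviant_cell_fraction"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class PileParams:
    """Divide-and-conquer pile sizing."""

    target_metacells_per_pile: int = 100
    min_pile_cells: int = 10_000
    max_pile_cells: int = 30_000
    # metagroup-phase partitions are sized in member *cells*, not UMIs:
    metagroup_min_cells: int = 5_000
    metagroup_max_cells: int = 12_500


@dataclass
class PipelineConfig:
    """Everything that controls a metacell run except the input and the seed."""

    target_umis: int = 160_000
    downsample_min_umis: int = 500       # lower clip of the downsampling target
    forbidden_genes: tuple[str, ...] = ()
    rare: RareModuleParams = field(default_factory=RareModuleParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    graph: GraphParams = field(default_factory=GraphParams)
    partition: PartitionParams = field(default_factory=PartitionParams)
    deviants: DeviantParams = field(default_factory=DeviantParams)
    piles: PileParams = field(default_factory=PileParams)

    def validate(self) -> None:
        if self.target_umis < 1:
            raise ValueError("target_umis must be positive")
        self.rare.validate()
        self.deviants.validate()

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
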
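# Methods

## The model

A *metacell* is a disjoint group of single-cell profiles treated as repeated
sparse samples from one multinomial transcriptional state.  Under that ideal,
for every gene the UMI counts of a metacell's member cells (at equal depth)
have variance ≈ mean, and the pooled profile is a maximum-likelihood estimate
of the state.  The package partitions a sparse cells × genes UMI matrix into
metacells plus a small set of *final outlier* cells that fit no group, and it
quantifies how closely each metacell follows the ideal.

The direct partitioning algorithm is quadratic in cells (it correlates all
cell pairs), so large inputs are processed divide-and-conquer style in
*piles* — subsets small enough for the direct algorithm — giving overall
O(N log N) work.

## The basic (per-pile) algorithm

1. **Downsampling.** Cells are subsampled without replacement (multivariate
   hypergeometric) to a common depth: the 5th percentile of per-cell totals,
   clipped to [500, U_targ] UMIs.  This removes depth as a confounder for
   feature selection and similarity.
2. **Feature election.** A gene is a feature iff it is not user-forbidden;
   its normalized variance (variance/mean over downsampled counts) exceeds by
   ≥ 0.1 the median of the 100 genes of most similar mean expression; it has
   ≥ 50 UMIs in the pile; and ≥ 4 UMIs in each of ≥ 3 cells.  Because
   election is per pile, late homogeneous piles automatically focus on genes
   separating sub-types.
3. **Balanced K-nn graph.** K = ⌈U_targ / median cell depth⌉ (the cells
   needed to reach the metacell UMI target).  Pearson correlations of
   log2(count+1) over feature genes are converted to directed similarity
   ranks (strongest neighbor of a cell gets rank value n−1), balanced as
   B[i,j] = √(R[i,j]·R[j,i]), pre-pruned to the top ⌈√10·K⌉ candidates per
   cell, then capped at 3K incoming and K outgoing edges per cell.  Balancing
   suppresses hub cells that would otherwise attract edges from everywhere.
   Cells with zero feature UMIs become isolated nodes and end up outliers.
4. **Two-sided stability partitioning** (below).
5. **Deviant (outlier) cell removal** (below), unless the pile runs in
   forced-coverage mode.

## The two-sided stability score

For a directed weighted graph G = (V, E, w) and partition mc, each node's
out-stability is the weight fraction of its outgoing edges that stay inside
its metacell, divided by the uniform baseline |M_mc(v)|/|V|; in-stability is
the same on incoming edges.  The score is the average of the log stabilities:

    score(mc) = 1/(2|V|) · Σ_v [ log(pstable_in/punif) + log(pstable_out/punif) ]

Logs are natural (the score is used ordinally).  Unlike modularity, a node
whose connectivity into its metacell is one-sided (say, only outgoing edges)
is penalized on the deficient side.  A node side with *no* internal weight
would contribute −∞; it contributes a floor constant of −10 instead, which
keeps candidate moves comparable while still strongly penalizing one-sided
membership.  The floor engages only at exactly zero internal weight; with
edge weights scaled into (0,1] any positive internal weight yields a log
stability far above −10.

**Optimization.** Seeds are sampled by exclusion (each new seed disconnected
from previous seeds and their neighbors; uniform fallback when exhausted),
P = ⌈Σ u′_v / U_targ⌉ of them, where u′_v = min(u_v, 2·median u) caps deep
cells.  Remaining nodes join the seed group with the strongest summed
balanced weight, growing outward in frontiers so nodes without a direct seed
edge are still assigned (ties and disconnected leftovers to the lowest
label).  Hill climbing then moves single nodes between metacells; at
annealing level λ a move of node v is accepted when Δscore + λ·Δ(v's own log
stabilities) > 0, with λ stepping through {4, 2, 1, 0.5, 0.25, 0}.  Move
evaluation is O(degree) per candidate metacell: the score decomposes into
per-side terms plus a per-metacell size term, with per-metacell counts of
floored sides tracked incrementally (numba kernel).  Sweeps visit nodes in
seeded random order; after a sweep, only the neighborhoods of moved nodes
are re-examined, and a full sweep confirms convergence.  If annealing ends
below the start score (rare), a plain λ=0 ascent from the start is used
instead, so the output never scores below the input.

**Size and connectivity control.**  With U_low = U_targ/2, U_high = 2·U_targ
(U_targ raised when the user value implies < 12 cells per metacell):

* *Max-size*: metacells with Σ u′ ≥ U_high dissolve; their cells are
  re-seeded (⌈Σ u′/U_targ⌉ seeds) and the partition re-optimized with the
  annealing bonus active only on dissolved nodes.
* *Connectivity*: each metacell's symmetrized subgraph is split by a global
  min cut (Stoer–Wagner; disconnected components short-circuit to a zero
  cut).  If the mean weight over crossing node pairs (missing edges count 0)
  is below 10% of the mean over non-crossing pairs, a small side (< 7 cells)
  is disassociated into outliers and the cut re-tested, otherwise the whole
  metacell dissolves.  Max-size and connectivity iterate (≤ 20 rounds) until
  stable.
* *Min-size*: metacells with Σ u′ ≤ U_low — or ≤ 0.5·U_low when the metacell
  carries a *marker gene*, one whose depth-normalized pooled expression is
  ≥ 8× the mean over metacells — and all metacells with < 12 cells dissolve;
  dissolved cells re-seed with one seed fewer than the number of dissolved
  metacells.  The loop (≤ 20 rounds) stops early, rolling back, if a round
  would create an oversized metacell.

In forced-coverage mode (outlier piles, metagroup grouping) no cell may be
left out: weak min-cut sides and undersized metacells merge into their
best-connected neighbor metacell instead of dissolving to outliers.

## Deviant (outlier) cells

For each cell and gene, the fold factor is (x+1)/(e+1) where e is the
metacell's pooled gene fraction scaled to the cell's total (computed on the
downsampled pile; singleton metacells are exempt).  Only over-expression is
tested.  Two thresholds adapt per pile:

* T_fold starts at 8 and doubles while more than 3% of the pile's genes have
  a maximal fold ≥ T_fold (denominator: all genes in the pile matrix).
* Per deviant gene, the cells whose fold reaches T_fold are ranked by
  descending fold (ties to the lower cell index); a cell's score is its
  minimal rank over deviant genes, and cells with score ≤ T_N are removed.
  This construction guarantees no single gene removes more than T_N cells.
  T_N starts at 1 and doubles while the removed set stays within 25% of the
  pile's cells.  Restricting ranks to cells at or above T_fold is what makes
  the T_N tuning meaningful: ranking all cells would let T_N grow until the
  25% cap is saturated by ordinary cells.

Removal iterates with recomputed pooled profiles until no new deviants
appear or the cumulative 25% budget is spent; metacells left under the
minimum size then dissolve entirely, and all removed cells become outliers
for the enclosing phase to regroup.

## Rare gene modules

States rarer than ~one cell per pile cannot form metacells under random
piling, and when their markers are weakly expressed they do not surface as
outliers either.  The pre-process runs once on the full matrix:

1. *Rare genes*: expressed (≥ 1 UMI) in ≤ 0.1% of cells yet with ≥ 7 UMIs in
   at least one cell.
2. *Correlation structure*: r = Pearson correlation of log2(count+1) between
   rare genes, restricted to cells expressing at least one rare gene; r2 =
   cor(r) scores genes by the similarity of their correlation *patterns*,
   which is far more stable than direct correlation for near-binary
   vectors.  Degenerate case: when a gene's correlation row is
   (near-)constant — e.g. every rare gene belongs to a single tight module,
   so all pairwise correlations are ~1 — its pattern carries no information
   and cor(r) amplifies floating-point noise; for pairs involving such genes
   the first-order correlation is used instead (row std ≤ 0.01).
3. *Candidate modules*: Ward clustering on (1 − r2); every maximal subtree
   with ≥ 4 genes and mean off-diagonal r2 ≥ 0.1.
4. *Expansion*: with C the cells expressing any seed gene, genes whose
   per-UMI frequency in C is ≥ 128× their global frequency join greedily (in
   descending enrichment) as long as the expressing-cell count stays below
   4·|C|.
5. *Module cells*: C^M = cells with ≥ 4 UMIs over the expanded genes.
   Modules with |C^M| < 12 (cannot form a metacell) or |C^M| > T are
   discarded, where T = 48 · n_cells / pile_size is the population size
   expected to place ~48 members in a random pile (such states survive
   piling on their own).  Cells claimed by several modules go to the module
   where they carry the most module UMIs.

Each surviving module's cells form a dedicated pile whose metacells pass
directly to the final output (provenance "rare"); its outliers rejoin the
main population.

## Divide and conquer

Pile size targets ~100 metacells per pile (configurable), clamped to
[10,000, 30,000] cells.  *Preliminary phase*: random piles (seeded shuffle,
near-equal splits), basic algorithm per pile, outliers pooled and re-piled
until one pile remains, which is partitioned with forced coverage — a
complete but low-quality cover.  *Metagroup phase*: each preliminary
metacell becomes one observation (pooled counts, weighted by member-cell
count) and the same machinery groups observations into metagroups of
5,000–12,500 member cells (sizing in cells, not UMIs; the bracket is set
directly rather than derived from a U_targ), recursing only when the
observations exceed one pile.  *Final phase*: each metagroup's cells form
one pile; outliers from all piles get exactly one regrouping round, after
which anything unassigned is a final outlier.

Per-pile random generators derive from the master seed and a (phase, level,
pile) key, so results are independent of pile execution order and
bit-reproducible.  Datasets that fit a single pile skip the three phases
(and the rare-module pre-process, which only exists to rescue states from
random piling): the pipeline output is then identical to the direct
algorithm by construction.

## QC metrics

*Inner normalized variance* (INV): member cells are downsampled to the
minimum member total (floor 100 UMIs); for genes with ≥ 40 total UMIs,
variance/mean is computed across members and the 95th percentile over genes
reported.  ≈ 1 under the multinomial ideal; mixing distinct states inflates
it.  Undefined (NaN) below 2 cells or with no qualifying gene.  For fair
comparison between solutions, metacell size distributions can be equalized
per annotated type by rank-matching sizes and subsampling to the rank
minimum across solutions.  Rare behaviors are characterized by per-gene
AUROC and fold enrichment for the cells of a module's metacells, by a
marker screen (genes ≥ 8-fold above the 99.8th percentile of the other
metacells' expression), and by module-UMI-fraction score distributions with
the positive threshold at 50% of the top group's median score.

## Synthetic data

The generator draws a shared heavy-tailed backbone (gamma(0.5) normalized),
elevates disjoint per-state marker blocks (default ~3% of genes per state)
by the `separation` fold, renormalizes, and samples each cell multinomially
at a log-normal depth (median 2,000 UMIs, σ = 0.4 in log space, truncated
to [500, 20,000] — mimicking common droplet preparations).  Planted rare
types rewrite `round(frequency·n)` cells from a profile whose module genes
(taken from the backbone's unexpressed tail, so the background is silent)
carry `enrichment` × the mean per-gene probability; at enrichment 50 and
median depth each module gene contributes ~50 UMIs per rare cell.  Planted
deviants raise one gene to `fold` × its expected count under the cell's
state profile — choosing genes with expectation ≥ 3 UMIs, because the +1
fold regularization caps achievable folds near the detection threshold
below that — and resample the cell back to its original depth.

What the generator does *not* emulate: doublets, ambient RNA, batch or
donor effects, continuous trajectories, or gene–gene correlation beyond the
discrete state structure.  Passing tests therefore demonstrate correctness
of the machinery under the model's own assumptions, not robustness to every
artifact of real preparations.

## Numerical and design choices

* Natural log throughout the score; floor constant −10 for zero internal
  weight; move acceptance threshold 1e-10.
* Similarity ties broken by cell index (stable sorts) for determinism.
* Downsampling target clip [500, U_targ]; QC downsampling floor 100 UMIs.
* Mitochondrial genes = case-insensitive "MT-" name prefix.
* The excluded-UMI fraction in filtering uses the cell's total over all
  genes before removal as denominator.
* Rare-module per-UMI frequencies (not fraction-of-cells) for the 128×
  expansion test.
* λ schedule {4, 2, 1, 0.5, 0.25, 0}; max 20 rounds for each control loop,
  then a warning is attached rather than looping forever.
* Stoer–Wagner min cut on the symmetrized subgraph; 2-cell metacells are
  skipped (no non-crossing pairs to compare against).

## Problem sizes used in the shipped checks

The test suite and acceptance script choose the largest sizes that keep a
complete run practical on one CPU: rare-type sensitivity at 150,000 cells
over a 1,000-gene space; partition
recovery at 40,000 cells from 8 states with 5,000–8,000-cell piles (pile
size is a user parameter; smaller piles trade a little quality for much
less work); score-oracle enumeration at 5–9 nodes exhaustively plus 100
twelve-node instances against the 2-part enumeration optimum; INV
calibration on 60-cell groups over 20 paired seeds.

## Known limitations

* Pile-level similarity is dense (cells × cells within a pile), so pile
  sizes beyond ~30,000 cells are memory-hungry — the same regime the
  divide-and-conquer design exists to avoid.
* The optimizer is a local search; tiny graphs with pathological weights
  can converge to local optima (observed rate < 5% on 12-node instances).
* The marker-gene exemption compares pooled, depth-normalized profiles with
  equal metacell weighting; very uneven metacell sizes shift the grand mean.
* Under-expression (drop-out) deviance is not tested, matching the method's
  over-expression-only definition.
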
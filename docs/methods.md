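# Methods

## Pipeline model and assumptions

The pipeline treats a brain as a fixed set of N micro-regions observed in
two modalities: a structural graph (nonnegative streamline counts) and a
functional correlation matrix (Pearson r in [−1, 1]), both square,
symmetric, with undefined — hence zero — diagonals. Population matrices are
the link-wise median over subjects, including zeros (a subject without a
streamline contributes 0 to that link's vector). Because SC is sparse and FC
dense, the functional population matrix is reduced to SC's link count K
before binarization: the K strongest positive correlations are kept
(ranking by signed value; ranking by |r| is available via
`fc_threshold="absolute"`). Links tied exactly with the K-th value are all
kept and counted, so the functional density can exceed the structural one by
the tie-group size; this is deterministic and avoids index-order
tie-breaking.

Fusion is affine: `γSFC = γ·FC + (1−γ)·SC` on the binary pair, so every
off-diagonal weight is 0, γ, 1−γ, or 1, and the endpoints reproduce each
modality bit-exactly. Only binary matrices are fused; weighted fusion is out
of scope.

## Hierarchy

Node dissimilarity is the correlation distance d(i,j) = 1 − Pearson(row_i,
row_j) over *full* connectivity rows (the self-columns, fixed at zero, stay
in; `exclude_self=True` drops columns i and j for the pair, at O(N³) cost).
A constant row makes the correlation undefined and raises an error naming
the node. Linkage is WPGMA ("weighted"): the distance from a merged cluster
to any other is the unweighted mean of its children's distances, which keeps
merge heights monotone. The implementation delegates to
`scipy.cluster.hierarchy.linkage`, whose nearest-neighbor-chain algorithm is
deterministic; under exact ties its merge order may differ from a naive
smallest-index agglomerator, which matters only for degenerate inputs (the
test oracle therefore uses continuous random matrices, where ties have
probability zero).

Cuts are defined by merge count, not height: cut(M) applies the first N−M
merges, so cut(M) always has exactly M modules and refines cut(M−1) by
splitting exactly one module, even under tied heights.

Tree metrics, at a reference cut:

* **MS** — leaves per module.
* **H** (per leaf) — the cut cardinality, counted from the top (M = 1 at the
  root), at which the leaf first stands alone; `h_direction="bottom_up"`
  returns N + 1 − H.
* **MH** — mean H over a module's members.
* **MSI** — the number of consecutive cut cardinalities a module survives,
  from the cut where it first appears as a module down to (and including)
  the cut at which it merges into its parent: with creating merge j (0 for
  leaves) and absorbing merge k (1-based), MSI = k − j + 1. The root module
  has MSI 1. `msi_mode="distance"` reports the merge-height interval
  instead of the level count. In the canonical chain tree over {a,b,c,d}
  this gives MSI({a,b}) = 2, H = (4,4,3,2), MH({a,b,c}) = 11/3.

## Cross-modularity

Q is Newman–Girvan modularity on a binary graph under a fixed partition:
Q = Σ_c [L_c/L − (d_c/2L)²]. Q_F and Q_S are evaluated on the binary FC and
SC matrices using the *fused-tree* partition — the only reading under which
χ depends on γ, since only the fused matrix is clustered. T_FS defaults to
the intra-module link-overlap DICE: per module, the DICE coefficient between
its linked node-pairs in FC and in SC, averaged over modules that have
intra-links in at least one modality (0 if none do). With a shared partition
the older node-set DICE is trivially 1; that variant
(`strategy="node-dice"`, which clusters FC and SC separately and matches
modules by maximal node-set DICE) is kept for comparability and is
γ-independent by construction. χ is the cube root of the product when all
three factors are nonnegative and NaN otherwise (excluded from the search,
logged).

The (γ, M) search defaults to γ ∈ {0.0, 0.1, …, 1.0} — the coarsest grid
that resolves one decimal — and M ∈ [2, min(120, N)]. Ties break toward
smaller M, then smaller γ (parsimony, determinism). Modules with fewer than
`min_module_size` = 3 leaves are counted as invalid at each cell, since one-
and two-region modules carry no internal community structure.

## Network metrics and annotation

Node strength is the fused row sum, normalized by the maximum (brain-map
convention; `normalization="n-1"` divides by the neighbor count instead).
Segregation of a module is the mean intra-module weight
Σ_{i≠j∈m} w_ij / (|m|(|m|−1)); singletons are NaN, not 0, so they never
enter metric correlations (Pearson r with two-sided p over modules,
requiring ≥ 3 complete rows). Atlas overlap is computed at element
granularity with optional per-element weights (voxel counts recover
voxel-level proportions without voxel data) as fraction-of-module (rows sum
to 1 over a covering atlas) or DICE.

## Neurogenetics

Sample expression is averaged within modules; each disorder set is matched
case-insensitively (exact symbols, no alias resolution — that needs an
external database), summarized per module by the mean (median via flag, as
the two conventions coexist in the field), and z-scored across modules with
the sample standard deviation (ddof = 1). |z| > 2 flags high/low modules;
zero variance yields NaN z and no flags. Disease groups pool the union of
member-disorder symbols (shared genes count once). Note the algebraic
ceiling max|z| = (m−1)/√m: with fewer than 6 modules no flag can ever fire,
and for finite m the null flag rate is the tail mass of an internally
studentized residual (z²·m/(m−1)² ~ Beta(1/2, (m−2)/2)), noticeably below
the asymptotic 2Φ(−2) ≈ 4.55% — e.g. 3.62% at m = 20. The calibration tests
check against this exact finite-m mass.

## Synthetic generator

The generator emulates what the pipeline assumes and nothing more: a common
modular skeleton expressed in both modalities with modality-specific noise.
SC subjects are planted-partition Bernoulli graphs — one backbone draw with
intra-module link probability `p_in`, inter `p_out`, then independent
per-subject link flips (`subject_flip_prob`). FC subjects are block
templates (`fc_block_mu_in` intra, `fc_block_mu_out` inter) plus iid
Gaussian noise, clipped to [−1, 1]; FC is drawn directly as a noisy block
correlation rather than via simulated BOLD series, which would add
parameters without adding test power. An optional nested level boosts
sub-module blocks. Expression is iid Normal(0, 1) with planted
(module, gene-set, effect) shifts in noise-sd units.

Reference conditions (the defaults): 60 nodes in 4 equal modules, 20
subjects, p_in = 0.8, p_out = 0.05, mu_in = 0.6, mu_out = 0.05, FC noise sd
0.1, flip probability 0.05 — a regime comparable to group-level human
connectome data in which the planted scale is recoverable but not trivially
so. What passing these tests does *not* show: real SC/FC share only part of
their modular structure, real noise is spatially correlated, and real
module sizes are heterogeneous; recovery on this generator demonstrates
correctness of the machinery, not expected performance on empirical
matrices.

## Numerical choices

* Symmetry tolerance 1e−8 on load: smaller asymmetries are averaged away,
  larger ones rejected (they usually mean misaligned node orders).
* Correlation distances are clipped to [0, 2] and merge heights to
  monotonicity, both against sub-1e-12 floating-point drift.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; cohort and expression use distinct
  seed streams so adding one does not shift the other.
* TSV floats are written at 17 significant digits, making write/read
  round-trips exact for IDs and within 1e−12 for values.

## Reported problem sizes

`scripts/acceptance.py` runs the reference study with M searched over
[2, 12], 50 random oracle instances at N ≤ 12, and the flag calibration over
200 replicates of 20 single-node modules × 12 gene sets (48 000 null
module–set pairs) — sizes at which every quantity is stable across seeds
while the whole script completes in seconds.

## Known limitations

* The published 2165-region optimum (γ\* = 0.7, 28 modules, 26 valid) can
  only be checked with the deposited population matrices on local disk; the
  corresponding test fails with download instructions when they are absent.
* The serialization of the deposited γ-trees is not covered; tree I/O is
  the package's own merge-table TSV and Newick export.
* No NIfTI/voxel handling, no BIDS parsing, no raw-MRI processing, no AHBA
  probe mapping — the package consumes matrices those stages produce.
* Only WPGMA linkage and tree-cut partitions are supported; alternative
  community detection (Louvain/Leiden) is deliberately out of scope.
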
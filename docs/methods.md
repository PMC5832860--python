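# Methods

This note documents the models and procedures implemented in `flowroute`,
the assumptions behind them, the defaults that matter, and the places where
the design was genuinely open and a choice had to be made.

## Assumptions

The pipeline assumes (i) that a single-cell snapshot of an asynchronously
evolving population captures all stages of the process at once, so an
ordering of cells can stand in for time; (ii) that the population is a
continuum of states organized into denser subpopulations; and (iii) that
expression changes along transitions are progressive, so smooth dynamics
along a good ordering are expected. Input expression is taken as already
log-normalized — the package never normalizes, and NaN input is an error
rather than something to impute. Matrices are genes × cells internally;
readers transpose on a flag. Duplicate gene symbols are collapsed by
averaging; zero-variance genes are removed before analysis.

## Graph construction and subpopulations

The kNN graph connects every cell to its k nearest neighbors in the
user-supplied embedding (Euclidean distance); distance ties break by
ascending cell id so results do not depend on input order. Edge weights are
then replaced by the Jaccard similarity of the endpoints' neighbor sets.
Neighbor sets include the cell itself, so two cells with identical
neighborhoods get weight exactly 1 — the standard shared-nearest-neighbor
convention. Zero-similarity edges are dropped and the graph becomes
undirected (an edge survives if it existed in either direction); for flow
analysis each undirected edge later becomes two opposite arcs of equal
capacity. Symmetrizing after (not before) the Jaccard transform is a
choice; the alternative changes neighbor sets only marginally at the same k.

Two separate k values are first-class parameters because the two tasks
want different resolutions: a smaller k yields a finer subpopulation
structure, while trajectory detection needs a connected graph, which
usually requires a larger k (defaults: k_subpop = 5, k_traj = 10; the
analyses in this repository's tests use k_subpop = 20 on 600-cell
simulations to capture major subpopulations, and k = 30 when the planted
structure is a small number of large, well-separated clusters — k must be
commensurate with expected cluster size or community detection resolves
sub-structure instead). The pipeline warns, with component sizes, when the
trajectory graph is disconnected, and fails with the component report when
a requested transition spans components.

Communities are found by seeded Louvain modularity maximization on the
similarity-weighted graph. Labels are canonicalized by decreasing community
size (ties by smallest member id), so label 1 is always the largest
subpopulation. Isolated cells end up as singleton subpopulations.

### Signature statistic

Subpopulation signatures use a binomial counting statistic on expressing
cells: for gene g and subpopulation P, K = number of cells in P with
expression > 0, N = |P|, and q = expressing fraction outside P; enrichment
is the upper tail P(X ≥ K | N, q), depletion the lower tail, with direction
taken from the sign of the mean-expression difference. A count-aggregation
variant (pooling rounded transcript counts across cells) was considered
and rejected: counts within a cell are not independent draws, which makes
that binomial badly overdispersed — in permutation experiments a planted
marker stayed "significant" in a quarter of label shuffles. The
expressing-cell statistic is calibrated under permutation and sends a gene
expressed identically everywhere to p = 1. Genes are reported only when
their expm1-scale mean fold change passes `min_fold` (default 1.5).

## Trajectories as minimum-cost flows

The flow network places capacity c(i,j) = Jaccard weight and cost
−log c(i,j) on every arc, so capacities in (0, 1] give non-negative costs
and weight-1 arcs cost exactly 0. Auxiliary source/sink nodes attach to the
chosen source cells S and target cells T with capacity-1, cost-0 arcs, so
maximum flow is min(|S|, |T|) at most — with the default one-source/
one-target selection, exactly 1 unit is routed. Source and target cells are
the most distant pair between the two subpopulations: among all
shortest paths (distance = −log similarity, consistent with the cost
structure) from each source-population cell to the target population, the
endpoints of the longest one are chosen, with lexicographic tie-breaking.

The solver scales capacities and costs by 10⁶ and rounds to integers for
an exact combinatorial min-cost-max-flow; 10⁻⁶ granularity is far below
the resolution of Jaccard weights at any practical k, and reported costs
are recomputed from the exact real costs afterwards. Verification compares
the solver against branch-and-bound enumeration of integral path
combinations on small instances; agreement is within the integerization
granularity (10⁻⁴ absolute on cost).

Flow decomposition into simple paths is not unique; we use greedy
widest-path decomposition (repeatedly extract the simple source→sink path
with maximal bottleneck flow). Restricting to simple paths also excludes
zero-cost cycles that weight-1 edges would otherwise permit. Each path is
annotated with its total flow (sum of the solution flow over its edges),
cost, and length (number of edges, auxiliary arcs stripped). Paths are
ranked by flow normalized to length by default; cost (ascending), flow
(descending) and length are selectable. For the length criterion the
longest path is preferred, consistent with selecting the most distant
endpoint cells: the trajectory should span the full transition.

Pseudotime is the normalized rank of each cell along the chosen path
(uniform spacing on [0, 1]), not cumulative cost: the method orders cells;
it does not claim a clock.

## Expression dynamics

Each path cell's expression is first replaced by the mean over the cell
and its graph neighbors (a fixed-neighborhood mean filter; it provably
never inflates per-gene variance along the path and mitigates drop-out
zeros). Genes are ranked by Spearman ρ against pseudotime; classes are
assigned from the empirical quantiles of the ρ distribution across
rankable genes — above the 0.85 quantile is "up", below the 0.15 quantile
"down" — rather than fixed ρ cut-offs, so roughly 15% of genes land in
each class by construction. Genes constant along the path have undefined ρ
and are excluded from the quantile computation. An absolute-ρ variant
would merge the two classes and is deliberately not used.

Kinetic trends are cubic smoothing splines with the smoothing parameter
chosen by generalized cross-validation (user-overridable), evaluated on a
uniform 500-point grid — resolution far above any realistic path length at
negligible cost. GCV needs at least five observations, so four-point
series (the minimum accepted) fall back to an interpolating cubic spline.
Rescaled curves map the smooth trend onto [0, 1]; constant trends are
flagged rather than divided by a zero range.

Trend distance is d(x,y) = 1 − ρ_pearson(x_smooth, y_smooth)/2, so d is in
[0.5, 1.5] and d(x,x) = 0.5 — the formula is kept as printed rather than
shifted to a zero-based metric, since only relative distances matter for
clustering. K-medoids uses a hand-written PAM (seeded random build plus
best-improvement swaps; no PAM implementation exists in the installed
stack) on the distance matrix of log(1+·)-transformed, per-gene z-scored
smooth curves. Input curves are already log-scale, so this is a second,
mild compression; Pearson correlation is scale-invariant, so the z-scoring
affects only the log transform's curvature, and the clustering is stable
to this choice. The number of clusters is user-defined.

Trajectory gene selection takes the union, over the first 5 principal
components, of genes whose absolute loading reaches the per-component
0.975 quantile — for a 1000-gene panel that is at most 125 genes.

## GRN reconstruction and regulator scoring

Cell-to-cell heterogeneity acts as a natural perturbation set, so
regulator–target dependencies are estimated as mutual information between
expression profiles across cells: a plug-in estimator in nats on
equal-frequency bins (default 10; at least ~50 cells are recommended and a
warning fires below that). Constant genes have MI 0 by convention.
MI(X,X) equals the binned entropy H(X) exactly. CLR z-scores each
regulator–gene MI value against the regulator's row background and the
gene's column background (negative z clipped at 0) and combines them as
√(z_r² + z_c²); edges at or above the threshold (default 3.0, exposed as a
flag since no canonical cut-off exists) are kept. This is the classic CLR
background correction; variants differ in details that are not material to
the ranking used here.

The regulator score multiplies the magnitude of the regulator's own
trajectory correlation, the mean correlation of its up-classified targets,
and their count: score = |c| · m · n. The magnitude (not the signed value)
is used because both mechanisms are biologically meaningful and should
rank high: a positively correlated regulator is an induction /
over-expression candidate, a negatively correlated one a de-repressor /
knock-down candidate — a signed product would bury de-repressors at the
bottom of the ranking. The sign is carried separately as `mechanism`.
"Targets regulated along the trajectory" means targets classified "up" by
the quantile rule; since all qualifying targets then have positive ρ,
signed and absolute target means coincide.

## Trajectory quality

Lag-1 autocorrelation is computed exactly as
r_t = c_t/c_0 with c_t = (1/n) Σ (x_{s+t} − x̄)(x_s − x̄) over the overlap
of the series with its lagged copy (general t is implemented; lag 1 is
surfaced). A constant series has c_0 = 0 and is an error at the metric
level, reported as missing at the report level. The quality report counts
up/down genes under the quantile rule and evaluates marker autocorrelation
on the neighborhood-smoothed series by default (a raw-series flag exists),
since smoothing is part of the kinetics the ordering is judged on. The
quantile rule is the only notion of "significantly correlated" used; no
p-value procedure is attached to it.

## Synthetic data

`simulate_branching` generates the study conditions used throughout the
tests: cells allocated uniformly at random among the branches of a linear,
bifurcating (A → B, C) or convergent (A, B → C) topology, uniform
pseudotime within branches, and a gene panel consisting of — per terminal
branch — one master regulator (sigmoid activation early in the branch)
driving 20 up-regulated targets whose sigmoids activate strictly later and
which share the regulator's noise term (coupling 0.6, which is what makes
the regulatory link visible to mutual information beyond the shared
pseudotime trend), one decoy regulator driving 2 targets, and 7 free
up-markers; 15 genes that decline from the root in every cell; 20 inert
regulators; and constant-baseline noise genes for the remainder. Gaussian
noise (sd 0.25 by default — visible but not overwhelming against sigmoid
amplitudes of 2–4) is added, values are floored at 0, and dropout zeroes
entries with probability dropout_rate · e^(−expression) (default rate 0.1),
concentrating technical zeros on low expression as in real data. The
embedding is the 2-D branch layout (branch length ≈ 5–7 units) with
Gaussian jitter of sd 0.30, or optionally a 2-component PCA of the
expression to exercise the full path. Everything is a deterministic
function of the seed. `simulate_clusters` (Gaussian blobs on a circle) and
`simulate_linear_grn` (a flat 20-edge regulator→target network with linear
activations plus noise) cover the community-detection and network-recovery
checks.

What the generator does **not** emulate: count noise and library-size
variation (values are log-scale abundances by construction), doublets,
batch effects, cell-cycle structure, and regulatory cascades deeper than
one level. Passing tests on these simulations demonstrates that the
algorithms recover planted structure under idealized but noisy conditions;
they do not certify performance on real data with those additional
artifacts.

Ground truth includes per-branch labels and a finer segmentation (each
branch split at its pseudotime midpoint). On a continuum, community
boundaries within a branch are not identifiable — strict ARI against the
midpoint segmentation plateaus around 0.65 at any resolution — so the
alignment check used in the tests merges found communities by majority
branch and computes ARI against branch labels (~0.85), which tests the
meaningful claim: communities do not straddle the bifurcation.

## Problem sizes and determinism

The test suite and the acceptance script run the central recovery analysis
at 600 cells × 500 genes (bifurcation) and 450 × 300 (convergence), sizes
at which every stage completes in seconds while leaving each subpopulation
tens of cells; the flow-optimality check uses 200 random networks of ≤ 8
cells plus auxiliary nodes, where exhaustive enumeration of integral path
combinations is tractable. All stochastic steps (simulation, Louvain, PAM
initialization) take explicit seeds, and identical configuration plus
inputs reproduce outputs byte-for-byte; the pipeline writes a manifest
with parameters, seed, package version and input checksums.

## Known limitations

- Trajectories are single paths between chosen endpoint cells; cells off
  the path receive no pseudotime, and no branching tree or probabilistic
  fate assignment is produced (transition-centeredness is the point, but it
  is a real restriction).
- The CLR network is undirected in nature; directionality comes solely
  from the user-supplied regulator list.
- The expressing-cell signature statistic loses power when a gene is
  expressed everywhere and only shifts in magnitude.
- Pseudotime is ordinal; distances along it carry no kinetic meaning.
- Equal-frequency MI binning with 10 bins is a bias/variance compromise;
  below ~100 cells the CLR backgrounds get noisy and the z threshold
  should be raised.
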
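# Methods

## Problem model

The solver treats the uncapacitated discrete p-median problem: `n` demand
points with non-negative weights `wᵢ` and planar coordinates, facilities
co-located with demand points (the candidate set defaults to all points),
and the objective `Z = Σᵢ wᵢ·d(i, a(i))` where `a(i)` is the nearest open
facility and `d` is Euclidean distance. Geographic inputs must be projected
to a planar CRS by the caller; no CRS handling is performed. The objective
is the weighted *sum* (the weighted mean differs only by the constant
`Σ wᵢ`, so both orderings of solutions coincide). Nearest-facility ties
break to the lowest facility index, making every evaluation deterministic.

The exact formulation is the standard location/assignment integer program:
binary `X_j` (open site `j`) and `Y_ij` (destination `i` served by `j`),
objective `Σ wᵢ d_ij Y_ij`, constraints `Σ_j Y_ij = 1` per destination,
`Σ_j X_j = p`, and disaggregated linking `Y_ij ≤ X_j`. It is solved with
HiGHS branch-and-cut through `scipy.optimize.milp`. The disaggregated
linking block keeps the LP relaxation tight; moderate instances
(n ≤ 300, p ≤ 30 by default) solve in seconds. A brute-force subset
enumeration (guarded at 10⁶ subsets) serves as the test oracle.

## Fast interchange

The local search is best-improvement vertex substitution: every swap of one
open facility against one closed candidate — exactly `p·(n_cand − p)` per
iteration — is evaluated, and the most negative objective change is
applied; the search stops when no swap improves. Swap deltas are computed
from nearest/second-nearest bookkeeping: for a destination not served by
the leaving facility the new distance is `min(d₁, d_enter)`, otherwise
`min(d₂, d_enter)`. This makes a sweep O((n_cand − p)·n) while remaining
arithmetically identical to naive re-evaluation (property-tested at 1e−9).
Improvements smaller than `1e−12·Z` are treated as zero so floating-point
noise cannot prevent termination. Ties break to the lowest entering, then
lowest leaving index.

Subproblem interchange runs inside the pipeline start from a deterministic
greedy (myopic add) solution rather than a random subset: the greedy start
is reproducible, lands in a good basin, and removes one source of run-to-run
variance; top-level interchange keeps the seeded uniform-random start so
that repeated restarts explore independent basins.

## Density-based decomposition

Mixtures are fitted on coordinates only — demand weights deliberately do
not influence the spatial clustering; they enter later through densities
and facility apportionment. EM uses full bivariate covariances,
k-means++-style initialisation with 5 restarts, tolerance 1e−4, at most 200
iterations and a 1e−6 covariance ridge (scikit-learn's GaussianMixture).
The free-parameter count is `6c − 1` (c−1 weights, 2c means, 3c covariance
entries), giving `BIC = ln(n)(6c−1) − 2 ln L̂`. The sweep runs `c = 2…c_max`
(default 20, capped at the number of distinct coordinates); `c = 1` is
never a decomposition candidate. BIC is known to drift towards larger `c`
on some distributions, which is why `c_max` is bounded and exposed rather
than adaptively extended.

## Merge step

A subregion earns an independent subproblem only if it is *dense* —
demand per unit convex-hull area strictly above the whole-region density
(degenerate hulls with fewer than three distinct points count as sparse) —
and *heterogeneous* under a quadrat χ² test. The test lays a near-square
grid of `N` equal cells over the subregion bounding box, counts cells with
exactly `i` of the `n_sub` points, and compares those frequencies with the
binomial expectation `E(i) = N·C(n_sub,i)p^i(1−p)^{n_sub−i}`, `p = 1/N`.
The statistic `Σ (E−F)²/E` is referred to a χ² distribution with `n_sub`
degrees of freedom. This degrees-of-freedom convention is unconventional
and markedly conservative (on uniform scatters the rejection rate is far
below the nominal 5%); it is retained deliberately and its conservatism is
asserted by a calibration test.

Two numerical details: the binomial support is truncated where the
remaining expected mass falls below 1e−9, with the residual folded into the
last bin so `Σ E(i) = N` holds exactly (observed counts beyond the cut fold
into the same bin); and the default cell count is
`N = max(9, ⌈n_sub/8⌉)` — an expected occupancy of about eight points per
cell. Quadrat tests need non-negligible expected counts per occupancy bin
to have any power; with one point per cell the conservative dof convention
rejects essentially nothing and smooth density gradients go undetected.
Both `N` and the significance level (default 0.05) are configuration.

Points of non-clustered subregions join the clustered subregion with the
nearest pre-merge centroid (all centroids frozen before any reassignment),
reducing `k` components to `q` subproblems that partition the point set and
conserve total demand exactly.

## Divide and conquer

Facility budgets are apportioned as `⌊p · demand share⌋` with leftovers
distributed one at a time in decreasing-demand order (ties by subregion
index, cycling), each budget capped at the subregion's member count with
overflow pushed down the order; `Σ p_sub = p` always. A budget of zero is
allowed — such a subregion's demand is served at conquer time. Subproblems
with `n_sub ≤ 300` and `p_sub ≤ 30` go to the MILP (the thresholds are
configuration; they bound the model at ~90 000 binaries), all others to
greedy-started fast interchange. Subproblems can run concurrently via
joblib; per-subproblem seeds derive from the master seed and the
subregion's demand rank, so results are identical for any worker count.
The facility union plus global nearest-facility reassignment is the
*reassignment* solution; global reassignment can only improve on the sum of
subproblem objectives. When one subproblem holds more than half the points
a warning is logged (recursive decomposition is not implemented).

When the mixture/merge stage finds no density clusters (fit failure, or
merge to `q = 1`), the divide step switches to a distance-based split of
the destinations — k-means with `k` chosen by the Davies–Bouldin index —
and the pipeline continues unchanged, including the MILP-or-interchange
choice per part. This replaces solving the undecomposed problem with one
cold interchange run; measured on centered instances it is both less
variable and slightly better.

## Distance-based decomposition

The iterative improvement stage clusters the *current facility sites* by
k-means (squared Euclidean, 10 restarts, sites unweighted), `k` selected
once by minimising the Davies–Bouldin index over `k = 2…k_max` (default
`min(20, ⌈√p⌉)`); each part solves its assigned destinations warm-started
from its own facilities, the union is reassigned globally, and `k`
decrements. The loop ends after the `k = 1` pass — a global warm-started
interchange — or as soon as the objective changes by less than 1e−9
relative between consecutive iterations. The objective is non-increasing
throughout: per-part interchange never worsens a part, and global
reassignment never worsens the union. For a fully homogeneous instance the
first iteration splits destinations instead of facilities, with
demand-proportional budgets and cold-started parts.

The Davies–Bouldin index is computed as specified for the selection rule:
scatter `Sᵢ` = mean member distance to the cluster centroid,
`R_ij = (Sᵢ+S_j)/‖centroidᵢ−centroid_j‖`, index = mean over clusters of
`max_{j≠i} R_ij`; coincident centroids raise an error. The in-package
implementation is cross-checked against scikit-learn's
`davies_bouldin_score` in the test suite.

## Synthetic instance generator

The generator emulates census-block-group construction: atomic demand
units scatter over a 256×256 cell grid (homogeneous: uniform; centered:
one Gaussian of spread 4× the blob spread at the grid centre; clustered:
a uniform mixture of 8 Gaussian blobs, spread 6 cells, centers
rejection-sampled to pairwise separation ≥ 10 spreads). Units snap to grid
cells. Destinations are then formed by drawing a target size from
N(1500, 400) truncated below at one unit (block-group-scale populations;
truncation keeps weights positive), seeding at a uniformly random
unassigned unit, and absorbing nearest unassigned units until the target is
met — implemented on per-cell counts with the final cell split, which is
equivalent because co-located units are interchangeable. The destination
sits at the centroid of its absorbed units and weighs their count, so
`Σ weights = total_demand` exactly under every seed. The facility count
defaults to `p = round(n/4)`.

What the generator does *not* emulate matters for interpreting results:
real block-group centroids are clumpy at many scales (street grids, zoning,
satellite towns), whereas aggregated truncated-normal patches produce a
near-regular tessellation whose quadrat statistics are close to binomial.
Consequently the homogeneity test engages less sharply here than on real
data, and passing benchmarks demonstrate pipeline correctness and quality
under idealised cluster structure, not performance on any particular
real region.

## Benchmark protocol and problem sizes

Quality is reported as relative cost, `100·Z/Z_best`, with `Z_best` the
minimum over 30 independent random-restart interchange runs (plus the
pipeline runs themselves for the centered condition, where they are part of
the stated baseline). The packaged conditions use total demands of 600 000
(clustered, ~400 destinations, p ≈ 100) and 450 000 (centered, ~300
destinations, p ≈ 75) — sizes chosen so a full protocol run completes in
minutes on one CPU while keeping `p = n/4` and block-group-scale demands.
On these conditions the reassignment-only pipeline stays within 2% of
best-known on clustered data and the improvement pipeline's median lands
within 0.5% on centered data; the exact figures are recomputed by
`scripts/acceptance.py` and the test suite rather than quoted here.

## Known limitations

- Distances are planar Euclidean; road networks and capacities are out of
  scope.
- BIC model selection can over-decompose single large clusters; the
  reassignment solution is then poor and only the improvement passes
  recover quality (the centered benchmark exercises exactly this regime).
- The quadrat test's `dof = n_sub` convention is conservative by
  construction; the cell-count default partially compensates but subtle
  heterogeneity still goes undetected.
- Recursive decomposition of a dominant subproblem is not implemented; a
  warning is emitted instead.
- The exact unit-to-destination merging rule of real block-group
  construction is not public; the nearest-unit absorption here is the
  package's own concrete realisation.
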
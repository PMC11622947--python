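# emfi — divide-and-conquer solver for large weighted p-median problems

`emfi` places `p` facilities among `n` weighted demand points on the plane so
that the demand-weighted sum of distances from every destination to its
nearest open facility,

```
Z = Σᵢ wᵢ · d(i, nearest open facility),
```

is minimised — the classic discrete **p-median** location-allocation model.
It is aimed at public-health and logistics planners who need solutions for
problems far beyond exact-solver reach (thousands of census-block-group
centroids, `p` in the hundreds), where even the standard fast-interchange
(vertex substitution) heuristic becomes slow.

## The algorithm

The solver divides the region before it conquers the optimisation:

1. **Density-based decomposition.** Demand-point coordinates are fitted with
   bivariate Gaussian mixtures by EM for component counts `c = 2…c_max`;
   each model is scored by `BIC = ln(n)·(6c−1) − 2·ln L̂` and the minimum-BIC
   model's maximum-posterior labels define `k` candidate subregions.
2. **Merge step.** A subregion is kept as an independent subproblem only if
   it is *dense* (demand per unit hull area above the whole-region density)
   and *heterogeneous* (a quadrat χ² test rejects uniform scatter: observed
   cell-occupancy frequencies `F(i)` against the binomial expectation
   `E(i) = N·C(n_sub,i)·p_cell^i(1−p_cell)^{n_sub−i}`, `p_cell = 1/N`, with
   `n_sub` degrees of freedom). Points of sparse or homogeneous subregions
   dissolve into the nearest clustered subregion, leaving `q ≤ k`
   subproblems.
3. **Divide and conquer.** Each subproblem receives
   `p_sub = ⌊p · demand share⌋` facilities (leftovers round-robin in
   decreasing demand order), is solved independently — exactly by a
   branch-and-cut MILP when small enough, by best-improvement fast
   interchange otherwise — and the facility union plus a global
   nearest-facility reassignment forms the *reassignment* solution.
4. **Improvement (optional).** Either one global warm-started fast
   interchange pass, or the iterative *distance-based decomposition*:
   k-means on the current facility sites (`k` chosen by the Davies–Bouldin
   index), warm-started per-part interchange, then `k → k−1` until the cost
   stalls or the final global pass at `k = 1`.

If the region has no density clusters the pipeline falls back to a
distance-based split of the destinations and continues identically.

## Worked example

Generate a 4-blob synthetic instance (60 000 demand units aggregated into
block-group-like destinations) and solve it:

```bash
$ emfi generate --layout clustered --total-demand 60000 --n-clusters 4 \
      --seed 7 --out demo.csv
wrote 39 destinations (p=10) to demo.csv

$ emfi solve --input demo.csv --p 10 --method emfi --improve global-fi \
      --seed 1 --out demo_sol
Z=260730.007017 -> demo_sol/summary.json
```

`summary.json` records the objective (`"objective": 260730.007…` — total
demand-weighted distance in grid units), the mixture component count
(`"k": 20`), the subproblem count after the merge (`"q": 4`), the fallback
path taken if any, and per-stage timings. `facilities.csv` lists the ten
selected sites, `assignment.csv` maps every destination to its facility
(the `weighted_distance` column sums exactly to `Z`), and
`--geojson areas.geojson` exports facility points and convex-hull service
areas for GIS viewers. An instance CSV has columns `id,x,y,demand` with
projected planar coordinates.

The same pipeline is available as a library:

```python
from emfi import SyntheticConfig, generate_instance, EmFiConfig, run_em_fi

instance, blob_labels = generate_instance(
    SyntheticConfig(layout="clustered", total_demand=600_000, seed=7))
solution, report, artifacts = run_em_fi(
    instance, EmFiConfig(seed=1, improve_mode="global_fi"))
```

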
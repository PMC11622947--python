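"""Divide-and-conquer p-median solver (the EM-FI pipeline).

Pipeline (the "EM-FI" algorithm):

1. *Divide* — fit Gaussian mixtures to the demand-point coordinates,
   select the component count by BIC, classify each component's subregion
   as clustered or not, and dissolve non-clustered subregions into the
   clustered ones (k components -> q subproblems).
2. *Apportion* — give each subproblem a facility budget proportional to its
   demand share (integer part), distributing the leftovers round-robin in
   decreasing order of demand.
3. *Conquer* — solve the subproblems independently (exact MILP when small
   enough, fast interchange otherwise), possibly concurrently; the union of
   the subproblem facilities plus a global nearest-facility reassignment is
   the *reassignment* solution.
4. *Improve* (optional) — one global warm-started fast-interchange pass, or
   the iterative distance-based decomposition.

When the region has no density clusters (the mixture/merge stage yields a
single subregion or fails), the pipeline falls back to an undecomposed
solve: a global interchange run, or the distance-based decomposition when
that improvement mode is selected.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from joblib import Parallel, delayed

from . import density_decomposition as dd
from . import merge_step as ms
from .exact_solver import solve_instance_exact
from .fast_interchange import fast_interchange, greedy_initial_solution
from .problem_core import PMedianInstance, Solution, SolverReport, evaluate_solution, relative_cost

__all__ = [
    "SubSolver",
    "SubproblemSpec",
    "EmFiConfig",
    "apportion_facilities",
    "choose_subsolver",
    "solve_subproblems",
    "conquer_reassign",
    "improve_global",
    "run_em_fi",
]

logger = logging.getLogger("emfi")


class SubSolver(str, Enum):
    MILP = "milp"
    FI = "fi"
    NONE = "none"  # p_sub == 0


@dataclass
class SubproblemSpec:
    members: np.ndarray  # global point indices
    p_sub: int
    solver: SubSolver
    seed: int | None = None


@dataclass
class EmFiConfig:
    """Tunables of the divide-and-conquer pipeline."""

    cmax: int = dd.DEFAULT_CMAX
    alpha: float = ms.DEFAULT_ALPHA
    chi2_cells: int | None = None  # None = auto (max(16, n_sub))
    milp_max_n: int = 300
    milp_max_p: int = 30
    milp_time_limit_s: float | None = 300.0
    workers: int = 1
    improve_mode: str = "none"  # none | global_fi | distance_decomposition
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.milp_max_n <= 0 or self.milp_max_p <= 0:
            raise ValueError("solver thresholds must be positive")
        if self.improve_mode not in ("none", "global_fi", "distance_decomposition"):
            raise ValueError(f"unknown improve_mode {self.improve_mode!r}")


def apportion_facilities(
    demands: list[float], p: int, member_counts: list[int]
) -> list[int]:
    """Split the facility budget p across subregions by demand share.

    Each subregion receives floor(p * demand_share); leftovers go one at a
    time to subregions in decreasing order of demand (ties by index),
    cycling until exhausted.  Budgets are capped at the subregion's member
    count, with overflow pushed down the demand order.
    """
    q = len(demands)
    if q == 0 or p < 1:
        raise ValueError("need p >= 1 and at least one subregion")
    if p > sum(member_counts):
        raise ValueError("infeasible cardinality: p exceeds total point count")
    total = float(sum(demands))
    shares = [int(np.floor(p * d / total)) for d in demands]
    # cap floors at capacity; excess rejoins the leftover pool
    for i in range(q):
        if shares[i] > member_counts[i]:
            shares[i] = member_counts[i]
    leftover = p - sum(shares)
    order = sorted(range(q), key=lambda i: (-demands[i], i))
    while leftover > 0:
        progressed = False
        for i in order:
            if leftover == 0:
                break
            if shares[i] < member_counts[i]:
                shares[i] += 1
                leftover -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by the capacity check
            raise ValueError("apportionment failed: no remaining capacity")
    return shares


def choose_subsolver(n_sub: int, p_sub: int, config: EmFiConfig) -> SubSolver:
    """Exact MILP for small subproblems, fast interchange otherwise."""
    if p_sub == 0:
        return SubSolver.NONE
    if n_sub <= config.milp_max_n and p_sub <= config.milp_max_p:
        return SubSolver.MILP
    return SubSolver.FI


def _solve_one(instance: PMedianInstance, spec: SubproblemSpec, config: EmFiConfig) -> np.ndarray:
    """Solve a single subproblem; returns global facility indices."""
    if spec.solver is SubSolver.NONE or spec.p_sub == 0:
        return np.empty(0, dtype=np.intp)
    try:
        sub = instance.subinstance(spec.members, p_sub=spec.p_sub)
        if spec.solver is SubSolver.MILP:
            result = solve_instance_exact(sub, time_limit=config.milp_time_limit_s)
            if result.solution is None:  # timeout with no incumbent
                sol, _ = fast_interchange(sub, initial_set=greedy_initial_solution(sub))
            else:
                sol = result.solution
        else:
            # deterministic greedy start: better basin and no subproblem noise
            sol, _ = fast_interchange(sub, initial_set=greedy_initial_solution(sub))
    except Exception as exc:
        raise RuntimeError(f"subproblem on {spec.members.size} points failed: {exc}") from exc
    return spec.members[sol.facilities]


def solve_subproblems(
    instance: PMedianInstance,
    specs: list[SubproblemSpec],
    workers: int = 1,
    seed: int | None = None,
) -> list[np.ndarray]:
    """Solve all subproblems, optionally in parallel.

    Per-subproblem seeds are derived from the master seed and the spec's
    position, so results do not depend on worker count or scheduling.
    """
    ss = np.random.SeedSequence(seed)
    for spec, child in zip(specs, ss.spawn(len(specs))):
        if spec.seed is None:
            spec.seed = int(child.generate_state(1)[0] % (2**31))
    config = EmFiConfig(workers=max(1, workers))
    if workers <= 1 or len(specs) <= 1:
        return [_solve_one(instance, spec, config) for spec in specs]
    return Parallel(n_jobs=workers, backend="loky")(
        delayed(_solve_one)(instance, spec, config) for spec in specs
    )


def conquer_reassign(
    instance: PMedianInstance, subproblem_facility_sets: list[np.ndarray]
) -> Solution:
    """Union the subproblem facilities and reassign every destination globally."""
    if subproblem_facility_sets:
        union = np.unique(np.concatenate([np.asarray(f, dtype=np.intp) for f in subproblem_facility_sets]))
    else:
        union = np.empty(0, dtype=np.intp)
    if union.size != instance.p:
        raise ValueError(
            f"apportionment breach: union has {union.size} facilities, expected {instance.p}"
        )
    return evaluate_solution(instance, union)


def improve_global(instance: PMedianInstance, solution: Solution) -> Solution:
    """One global fast-interchange pass warm-started at the given solution."""
    improved, _ = fast_interchange(instance, initial_set=solution.facilities)
    return improved


@dataclass
class EmFiArtifacts:
    """Per-stage outputs of a pipeline run, for inspection and logging."""

    k_components: int | None = None
    q_subregions: int | None = None
    fallback: str | None = None  # None, "homogeneous" or "decomposition_failed"
    reassignment: Solution | None = None
    specs: list[SubproblemSpec] = field(default_factory=list)
    stage_seconds: dict = field(default_factory=dict)
    distance_trace: object | None = None


def run_em_fi(
    instance: PMedianInstance,
    config: EmFiConfig | None = None,
    baseline: float | None = None,
) -> tuple[Solution, SolverReport, EmFiArtifacts]:
    """Run the full divide-and-conquer pipeline on an instance."""
    config = config or EmFiConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_em, seed_sub, seed_fallback, seed_ddc = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    art = EmFiArtifacts()
    t0 = time.perf_counter()

    # ---- divide: mixture fit + merge ----
    subregions: list[ms.Subregion] | None = None
    try:
        _, labeling, k = dd.select_component_model(
            instance.coords, c_max=config.cmax, seed=seed_em
        )
        art.k_components = k
        raw = ms.build_subregions(instance.coords, instance.weights, labeling.labels)
        region_density = ms.region_demand_density(instance.coords, instance.weights)
        ms.classify_subregions(
            raw, instance.coords, region_density, alpha=config.alpha, n_cells=config.chi2_cells
        )
        subregions = ms.merge_nonclustered(raw, instance.coords, instance.weights)
        if len(subregions) == 1:
            art.fallback = "homogeneous"
            subregions = None
    except ValueError as exc:
        logger.info("density decomposition unavailable: %s", exc)
        art.fallback = (
            "homogeneous" if "homogeneous" in str(exc) else "decomposition_failed"
        )
        subregions = None
    art.stage_seconds["divide"] = time.perf_counter() - t0

    if subregions is None:
        # ---- fallback: no density clusters; divide by distance instead.
        # The subregions come from a k-means split of the destinations (k by
        # the Davies-Bouldin index) and rejoin the normal conquer path.
        t1 = time.perf_counter()
        from .distance_decomposition import _kmeans, default_k_max, select_partition_count

        k_split = select_partition_count(
            instance.coords, default_k_max(instance.p), seed_fallback
        )
        split_labels = _kmeans(instance.coords, k_split, seed_fallback)
        subregions = ms.build_subregions(instance.coords, instance.weights, split_labels)
        art.stage_seconds["fallback_divide"] = time.perf_counter() - t1

    art.q_subregions = len(subregions)
    biggest = max(s.members.size for s in subregions)
    if biggest > instance.n / 2:
        logger.warning(
            "one subproblem holds %d of %d points; consider recursive decomposition",
            biggest,
            instance.n,
        )

    # ---- apportion + conquer ----
    t1 = time.perf_counter()
    demands = [s.total_demand for s in subregions]
    counts = [s.members.size for s in subregions]
    p_subs = apportion_facilities(demands, instance.p, counts)
    # seed order follows decreasing demand so scheduling cannot matter
    rank = sorted(range(len(subregions)), key=lambda i: (-demands[i], i))
    spec_seeds = {
        i: int(c.generate_state(1)[0] % (2**31))
        for i, c in zip(rank, np.random.SeedSequence(seed_sub).spawn(len(subregions)))
    }
    specs = [
        SubproblemSpec(
            members=s.members,
            p_sub=p_sub,
            solver=choose_subsolver(s.members.size, p_sub, config),
            seed=spec_seeds[i],
        )
        for i, (s, p_sub) in enumerate(zip(subregions, p_subs))
    ]
    art.specs = specs
    facility_sets = solve_subproblems(instance, specs, workers=config.workers, seed=seed_sub)
    art.stage_seconds["conquer"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    solution = conquer_reassign(instance, facility_sets)
    art.reassignment = solution
    art.stage_seconds["reassign"] = time.perf_counter() - t2

    # ---- improvement ----
    t3 = time.perf_counter()
    if config.improve_mode == "global_fi":
        solution = improve_global(instance, solution)
    elif config.improve_mode == "distance_decomposition":
        from .distance_decomposition import iterate_distance_decomposition

        solution, trace = iterate_distance_decomposition(instance, solution, seed=seed_ddc)
        art.distance_trace = trace
    art.stage_seconds["improve"] = time.perf_counter() - t3

    report = SolverReport(
        method=f"em-fi:{config.improve_mode}",
        objective=solution.objective,
        relative_cost_percent=relative_cost(solution.objective, baseline)
        if baseline
        else None,
        seed=config.seed,
        extra={"k": art.k_components, "q": art.q_subregions, "fallback": art.fallback},
    )
    for stage, secs in art.stage_seconds.items():
        logger.info("stage=%s q=%s k=%s Z=%.6g elapsed=%.3fs",
                    stage, art.q_subregions, art.k_components, solution.objective, secs)
    return solution, report, art
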
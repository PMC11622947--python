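"""Iterative distance-based decomposition.

Refinement for solutions whose region lacks density clusters (or as a
cheaper alternative to one global interchange pass): the *current facility
sites* are partitioned into k groups by k-means — a destination far from a
facility is unlikely to be served by it, so each group plus the destinations
currently assigned to its facilities forms a warm-started subproblem.  The
subproblems are solved with the fast-interchange heuristic, the facility
union is reassigned globally, and the procedure repeats with k-1 groups
until k = 1 (a global warm-started interchange pass) or until the objective
stalls across two consecutive iterations.

The initial k is chosen by the Davies-Bouldin index over k = 2..k_max:
with per-cluster scatter S_i (mean member distance to the centroid) and
centroid separation d_ij, the index is the mean over clusters of
max_{j != i} (S_i + S_j) / d_ij; lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .fast_interchange import fast_interchange
from .problem_core import PMedianInstance, Solution, evaluate_solution

__all__ = [
    "FacilityPartition",
    "davies_bouldin_index",
    "select_partition_count",
    "build_facility_subproblems",
    "iterate_distance_decomposition",
]

DEFAULT_STALL_TOL = 1e-9
_KMEANS_N_INIT = 10


@dataclass
class FacilityPartition:
    k: int
    facility_labels: np.ndarray  # part label per facility (aligned with facilities)
    facilities: np.ndarray  # sorted facility point indices
    part_facilities: list[np.ndarray]  # facility indices per part (warm starts)
    part_destinations: list[np.ndarray]  # destination indices per part

    @property
    def part_sizes(self) -> list[int]:
        return [f.size for f in self.part_facilities]


@dataclass
class DecompositionTrace:
    k_sequence: list[int] = field(default_factory=list)
    objective_sequence: list[float] = field(default_factory=list)
    stalled: bool = False


def davies_bouldin_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin cluster-quality index (lower = better separated)."""
    x = np.asarray(points, dtype=float)
    labs = np.asarray(labels)
    uniq = np.unique(labs)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    centroids = np.array([x[labs == u].mean(axis=0) for u in uniq])
    scatter = np.array(
        [np.linalg.norm(x[labs == u] - c, axis=1).mean() for u, c in zip(uniq, centroids)]
    )
    sep = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    if np.any(sep[~np.eye(uniq.size, dtype=bool)] == 0):
        raise ValueError("degenerate clustering: coincident centroids")
    with np.errstate(divide="ignore", invalid="ignore"):  # diagonal is 0/0, discarded below
        r = (scatter[:, None] + scatter[None, :]) / sep
    np.fill_diagonal(r, -np.inf)
    return float(np.mean(np.max(r, axis=1)))


def _kmeans(coords: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=_KMEANS_N_INIT, random_state=seed)
    return km.fit_predict(coords)


def select_partition_count(
    facility_coords: np.ndarray, k_max: int, seed: int | None = None
) -> int:
    """k minimising the Davies-Bouldin index over k-means runs, k = 2..k_max."""
    coords = np.asarray(facility_coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 facilities")
    if k_max < 2:
        raise ValueError("invalid k_max")
    k_cap = min(k_max, coords.shape[0], np.unique(coords, axis=0).shape[0])
    if k_cap < 2:
        return 2
    ss = np.random.SeedSequence(seed)
    best_k, best_idx = 2, np.inf
    for k, child in zip(range(2, k_cap + 1), ss.spawn(k_cap - 1)):
        labels = _kmeans(coords, k, int(child.generate_state(1)[0] % (2**31)))
        try:
            idx = davies_bouldin_index(coords, labels)
        except ValueError:
            continue
        if idx < best_idx:
            best_k, best_idx = k, idx
    return best_k


def default_k_max(p: int) -> int:
    return max(2, min(20, int(np.ceil(np.sqrt(p)))))


def build_facility_subproblems(
    instance: PMedianInstance, solution: Solution, k: int, seed: int | None = None
) -> FacilityPartition:
    """Partition the current facilities into k parts with their service areas.

    Each part carries the destinations currently assigned to its facilities,
    so parts partition both the facility set and the destination set.
    """
    fac = solution.facilities
    if fac.size < k:
        raise ValueError("degenerate partition: fewer facilities than parts")
    coords = instance.coords[fac]
    ss = np.random.SeedSequence(seed)
    labels = None
    for child in ss.spawn(5):  # bounded retries against empty parts
        cand = _kmeans(coords, k, int(child.generate_state(1)[0] % (2**31)))
        if np.unique(cand).size == k:
            labels = cand
            break
    if labels is None:
        raise ValueError("degenerate partition")
    part_fac = [fac[labels == part] for part in range(k)]
    fac_to_part = {int(f): part for part, fs in enumerate(part_fac) for f in fs}
    assign_part = np.array([fac_to_part[int(j)] for j in solution.assignment])
    # a facility always belongs to its own part's destination set, even if a
    # coincident lower-index facility serves it
    assign_part[fac] = labels
    part_dest = [np.flatnonzero(assign_part == part) for part in range(k)]
    return FacilityPartition(
        k=k,
        facility_labels=labels,
        facilities=fac,
        part_facilities=part_fac,
        part_destinations=part_dest,
    )


def _solve_parts_warm(
    instance: PMedianInstance,
    partition: FacilityPartition,
) -> np.ndarray:
    """Fast interchange on every part, warm-started at the part's facilities."""
    union: list[int] = []
    for fac_part, dest_part in zip(partition.part_facilities, partition.part_destinations):
        if fac_part.size == 0:
            continue
        if dest_part.size == fac_part.size:
            union.extend(int(j) for j in dest_part)
            continue
        sub = instance.subinstance(dest_part, p_sub=fac_part.size)
        local_warm = np.searchsorted(dest_part, fac_part)
        sol, _ = fast_interchange(sub, initial_set=local_warm)
        union.extend(int(dest_part[j]) for j in sol.facilities)
    return np.sort(np.asarray(union, dtype=np.intp))


def iterate_distance_decomposition(
    instance: PMedianInstance,
    solution: Solution | None,
    seed: int | None = None,
    k_max: int | None = None,
    stall_tol: float = DEFAULT_STALL_TOL,
) -> tuple[Solution, DecompositionTrace]:
    """Run the k -> k-1 decomposition loop from a warm solution.

    With ``solution=None`` (the fully homogeneous fallback) the first
    iteration instead partitions *destinations* by k-means, apportions
    facilities to parts proportionally to demand, and solves each part with
    a cold-started interchange; subsequent iterations proceed on facilities
    as usual.  Terminates at the k = 1 pass (a global warm-started
    interchange) or as soon as the objective is unchanged across two
    consecutive iterations.
    """
    from .divide_conquer import apportion_facilities  # cyclic at import time

    ss = np.random.SeedSequence(seed)
    seeds = iter(int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(64))
    trace = DecompositionTrace()

    if solution is None:
        # homogeneous fallback: first split is on destinations
        k0 = select_partition_count(
            instance.coords, k_max or default_k_max(instance.p), next(seeds)
        )
        labels = _kmeans(instance.coords, k0, next(seeds))
        parts = [np.flatnonzero(labels == part) for part in range(k0)]
        demands = [float(instance.weights[m].sum()) for m in parts]
        p_parts = apportion_facilities(demands, instance.p, [m.size for m in parts])
        union: list[int] = []
        for members, p_part in zip(parts, p_parts):
            if p_part == 0:
                continue
            sub = instance.subinstance(members, p_sub=p_part)
            sol, _ = fast_interchange(sub, seed=next(seeds))
            union.extend(int(members[j]) for j in sol.facilities)
        solution = evaluate_solution(instance, union)
        trace.k_sequence.append(k0)
        trace.objective_sequence.append(solution.objective)
        k = k0 - 1
    else:
        k = select_partition_count(
            instance.coords[solution.facilities],
            k_max or default_k_max(instance.p),
            next(seeds),
        )

    prev_obj = solution.objective
    while k >= 1:
        if k == 1:
            sol, _ = fast_interchange(instance, initial_set=solution.facilities)
            solution = sol
            trace.k_sequence.append(1)
            trace.objective_sequence.append(solution.objective)
            break
        partition = build_facility_subproblems(instance, solution, k, next(seeds))
        union = _solve_parts_warm(instance, partition)
        solution = evaluate_solution(instance, union)
        trace.k_sequence.append(k)
        trace.objective_sequence.append(solution.objective)
        if abs(prev_obj - solution.objective) <= stall_tol * max(1.0, abs(prev_obj)):
            trace.stalled = True
            break
        prev_obj = solution.objective
        k -= 1
    return solution, trace
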
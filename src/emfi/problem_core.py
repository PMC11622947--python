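"""Core p-median problem model.

The (uncapacitated, discrete) p-median problem: given n demand points with
non-negative weights ``w_i`` and a set of candidate facility sites (here
co-located with the demand points), choose exactly ``p`` facilities so that
the demand-weighted sum of distances from every destination to its nearest
open facility,

    Z = sum_i w_i * d(i, nearest open facility),

is minimised.  This module holds the instance/solution containers, the
objective and assignment semantics, the relative-cost evaluation protocol,
and a brute-force enumeration oracle used by the test suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DemandPoint",
    "PMedianInstance",
    "Solution",
    "SolverReport",
    "pairwise_distances",
    "evaluate_solution",
    "relative_cost",
    "brute_force_optimum",
]

#: subset-enumeration guard for the exact oracle
_ORACLE_MAX_SUBSETS = 10**6


@dataclass(frozen=True)
class DemandPoint:
    """A destination: a planar location carrying a non-negative demand weight."""

    id: object
    x: float
    y: float
    weight: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"demand point {self.id!r}: coordinates must be finite")
        if not math.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"demand point {self.id!r}: weight must be >= 0")


class PMedianInstance:
    """An n-point weighted p-median instance on the plane.

    Facilities are co-located with demand points: the candidate set is a
    subset of point indices (default: all points).  Distances are planar
    Euclidean; geographic coordinates must be projected by the caller.
    """

    def __init__(
        self,
        points: Sequence[DemandPoint],
        p: int,
        candidates: Sequence[int] | None = None,
    ) -> None:
        points = list(points)
        if not points:
            raise ValueError("empty instance")
        ids = [pt.id for pt in points]
        if len(set(ids)) != len(ids):
            raise ValueError("point ids must be unique")
        if candidates is None:
            candidates = range(len(points))
        cand = np.unique(np.asarray(list(candidates), dtype=np.intp))
        if cand.size == 0 or cand.min() < 0 or cand.max() >= len(points):
            raise ValueError("candidates must be valid point indices")
        if not (1 <= p <= cand.size):
            raise ValueError(
                f"cardinality violation: need 1 <= p <= |candidates|, "
                f"got p={p}, |candidates|={cand.size}"
            )
        self.points: list[DemandPoint] = points
        self.p = int(p)
        self.candidates = cand
        self.coords = np.array([[pt.x, pt.y] for pt in points], dtype=float)
        self.weights = np.array([pt.weight for pt in points], dtype=float)
        self._dist: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def ids(self) -> list:
        return [pt.id for pt in self.points]

    def distance_matrix(self) -> np.ndarray:
        """Full symmetric n x n Euclidean distance matrix (cached)."""
        if self._dist is None:
            self._dist = pairwise_distances(self.coords)
        return self._dist

    def subinstance(self, member_indices: Sequence[int], p_sub: int) -> "PMedianInstance":
        """Restrict to a subset of points; candidates become all members."""
        members = np.asarray(member_indices, dtype=np.intp)
        return PMedianInstance([self.points[i] for i in members], p_sub)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PMedianInstance(n={self.n}, p={self.p}, |cand|={self.candidates.size})"


@dataclass
class Solution:
    """A size-p facility set with its nearest-facility assignment and objective."""

    facilities: np.ndarray  # sorted point indices, length p
    assignment: np.ndarray  # destination index -> facility point index
    objective: float

    def facility_set(self) -> frozenset:
        return frozenset(int(j) for j in self.facilities)


@dataclass
class SolverReport:
    """Bookkeeping for a solver run: method, objective, cost relative to a baseline."""

    method: str
    objective: float
    relative_cost_percent: float | None = None
    iterations: int = 0
    wall_time_s: float = 0.0
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def pairwise_distances(points: np.ndarray | Sequence) -> np.ndarray:
    """Symmetric matrix of Euclidean distances d_ij between all point pairs."""
    coords = np.asarray(points, dtype=float)
    if coords.ndim != 2:
        coords = np.atleast_2d(coords)
    if coords.shape[0] == 0:
        raise ValueError("empty instance")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    d = cdist(coords, coords)
    np.fill_diagonal(d, 0.0)
    return d


def assign_nearest(
    dist: np.ndarray, facilities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each destination to its nearest facility.

    Ties are broken by the lowest facility index: ``facilities`` is sorted
    ascending and ``argmin`` keeps the first minimiser.
    """
    fac = np.sort(np.asarray(facilities, dtype=np.intp))
    sub = dist[:, fac]
    col = np.argmin(sub, axis=1)
    return fac[col], sub[np.arange(sub.shape[0]), col]


def evaluate_solution(instance: PMedianInstance, facility_set: Iterable[int]) -> Solution:
    """Build the Solution induced by a facility set under nearest assignment."""
    fac = np.sort(np.unique(np.asarray(list(facility_set), dtype=np.intp)))
    if fac.size != instance.p:
        raise ValueError(
            f"cardinality violation: |facilities|={fac.size}, expected p={instance.p}"
        )
    if not np.isin(fac, instance.candidates).all():
        raise ValueError("facility set contains non-candidate indices")
    assignment, dmin = assign_nearest(instance.distance_matrix(), fac)
    objective = float(np.dot(instance.weights, dmin))
    return Solution(facilities=fac, assignment=assignment, objective=objective)


def relative_cost(objective: float, best_known: float) -> float:
    """Cost relative to the best-known objective, as a percentage (100 = match)."""
    if best_known <= 0:
        raise ValueError("invalid baseline: best_known must be > 0")
    return 100.0 * objective / best_known


def brute_force_optimum(instance: PMedianInstance) -> Solution:
    """Exact optimum by enumerating every size-p candidate subset.

    Deterministic: subsets are visited in lexicographic order and a strict
    improvement is required to replace the incumbent, so ties resolve to the
    lexicographically smallest optimal facility set.  Guarded against
    combinatorial blow-up; intended as a test oracle for small instances.
    """
    n_cand, p = instance.candidates.size, instance.p
    if math.comb(n_cand, p) > _ORACLE_MAX_SUBSETS:
        raise ValueError("instance too large for oracle")
    dist = instance.distance_matrix()
    w = instance.weights
    best_obj = math.inf
    best_fac: tuple[int, ...] | None = None
    for subset in itertools.combinations(instance.candidates.tolist(), p):
        dmin = dist[:, subset].min(axis=1)
        obj = float(np.dot(w, dmin))
        if obj < best_obj:
            best_obj = obj
            best_fac = subset
    assert best_fac is not None
    return evaluate_solution(instance, best_fac)
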
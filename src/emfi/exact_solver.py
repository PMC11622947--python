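"""Integer-programming formulation of the p-median problem.

Standard ReVelle–Swain style formulation.  Binary location variables X_j
(open a facility at candidate j) and assignment variables Y_ij (destination
i served by candidate j):

    min  sum_i sum_j w_i * d_ij * Y_ij
    s.t. sum_j Y_ij = 1          for every destination i     (single service)
         sum_j X_j  = p                                      (cardinality)
         Y_ij <= X_j             for every i, j              (linking)

The model is solved with a branch-and-cut MILP backend; the default backend
is HiGHS via :func:`scipy.optimize.milp`.  The linking constraints are kept
disaggregated — the LP relaxation is tight enough that moderate instances
solve quickly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .problem_core import PMedianInstance, Solution, evaluate_solution

__all__ = ["LipModel", "build_lip", "solve_exact", "solve_instance_exact"]


@dataclass
class LipModel:
    """Assembled integer program: objective vector plus constraint blocks.

    Variable layout: ``[X_0..X_{m-1}, Y_00..Y_{n-1,m-1}]`` with m candidate
    columns; Y is row-major over (destination, candidate).
    """

    instance: PMedianInstance
    objective: np.ndarray
    constraints: list[LinearConstraint]
    n_x: int
    n_y: int

    @property
    def n_variables(self) -> int:
        return self.n_x + self.n_y

    @property
    def n_constraints(self) -> int:
        return sum(c.A.shape[0] for c in self.constraints)


def build_lip(instance: PMedianInstance) -> LipModel:
    """Assemble the location/assignment integer program for an instance."""
    n = instance.n
    cand = instance.candidates
    m = cand.size
    if instance.p > m:
        raise ValueError("infeasible cardinality: p > |candidates|")
    dist = instance.distance_matrix()[:, cand]  # n x m
    cost = (instance.weights[:, None] * dist).ravel()  # Y coefficients
    c = np.concatenate([np.zeros(m), cost])

    n_y = n * m
    # block 1: each destination assigned to exactly one facility
    rows = np.repeat(np.arange(n), m)
    cols = m + np.arange(n_y)
    a_assign = sparse.csr_matrix((np.ones(n_y), (rows, cols)), shape=(n, m + n_y))
    # block 2: exactly p facilities
    a_card = sparse.csr_matrix(
        (np.ones(m), (np.zeros(m, dtype=int), np.arange(m))), shape=(1, m + n_y)
    )
    # block 3: Y_ij <= X_j  (linking)
    link_rows = np.arange(n_y)
    y_cols = m + link_rows
    x_cols = np.tile(np.arange(m), n)
    a_link = sparse.csr_matrix(
        (
            np.concatenate([np.ones(n_y), -np.ones(n_y)]),
            (np.concatenate([link_rows, link_rows]), np.concatenate([y_cols, x_cols])),
        ),
        shape=(n_y, m + n_y),
    )
    constraints = [
        LinearConstraint(a_assign, 1.0, 1.0),
        LinearConstraint(a_card, float(instance.p), float(instance.p)),
        LinearConstraint(a_link, -np.inf, 0.0),
    ]
    return LipModel(instance=instance, objective=c, constraints=constraints, n_x=m, n_y=n_y)


@dataclass
class ExactResult:
    solution: Solution | None
    optimal: bool
    bound: float | None
    status: str


def solve_exact(model: LipModel, time_limit: float | None = None) -> ExactResult:
    """Solve the assembled program by branch and cut (HiGHS backend).

    Returns the incumbent solution, an optimality flag and the best proven
    lower bound.  On timeout the incumbent (if any) is returned with the
    flag false.
    """
    options: dict = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    integrality = np.ones(model.n_variables)
    res = milp(
        c=model.objective,
        constraints=model.constraints,
        integrality=integrality,
        bounds=(0, 1),
        options=options,
    )
    if res.status == 2:  # infeasible
        raise ValueError("infeasible model")
    bound = float(res.mip_dual_bound) if res.mip_dual_bound is not None else None
    if res.x is None:
        return ExactResult(solution=None, optimal=False, bound=bound, status=res.message)
    inst = model.instance
    x = res.x[: model.n_x]
    fac = inst.candidates[x > 0.5]
    if fac.size != inst.p:
        # numerical fuzz: take the p largest X values
        fac = inst.candidates[np.argsort(-x, kind="stable")[: inst.p]]
    solution = evaluate_solution(inst, fac)
    optimal = bool(res.status == 0)
    return ExactResult(solution=solution, optimal=optimal, bound=bound, status=res.message)


def solve_instance_exact(
    instance: PMedianInstance, time_limit: float | None = None
) -> ExactResult:
    """Convenience wrapper: build the program and solve it."""
    return solve_exact(build_lip(instance), time_limit=time_limit)
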
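"""Benchmark protocols on synthetic instances.

Quality is always reported relative to the best-known objective for the
instance: the minimum over repeated random-restart fast-interchange runs
(30 by default), the exact MILP optimum when the instance is small enough
to solve, and — where stated — the evaluated pipeline runs themselves.
Relative cost is 100 * Z / Z_best, so 100 means "matches the best known".

Two standard study conditions are packaged:

* ``clustered_benchmark`` — 8 well-separated Gaussian blobs, ~400
  destinations, p = n/4; measures the divide-and-conquer *reassignment*
  solution (no improvement pass) over several pipeline seeds.
* ``centered_benchmark`` — one central Gaussian blob, ~300 destinations,
  p = n/4; measures the pipeline with the global-interchange *improvement*
  pass, the regime the decomposition finds hardest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .divide_conquer import EmFiConfig, run_em_fi
from .fast_interchange import fast_interchange
from .problem_core import PMedianInstance, relative_cost
from .synthetic_data import SyntheticConfig, generate_instance

__all__ = ["BenchmarkResult", "clustered_benchmark", "centered_benchmark", "best_known_fi"]


@dataclass
class BenchmarkResult:
    n: int
    p: int
    best_known: float
    objectives: list[float]
    relative_costs: list[float] = field(default_factory=list)

    @property
    def worst_relative(self) -> float:
        return max(self.relative_costs)

    @property
    def median_relative(self) -> float:
        return float(np.median(self.relative_costs))


def _derive_seeds(master_seed: int, n: int, stream: int) -> list[int]:
    ss = np.random.SeedSequence([int(master_seed), stream])
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def best_known_fi(instance: PMedianInstance, master_seed: int, n_restarts: int = 30) -> float:
    """Best objective over independent random-restart interchange runs."""
    seeds = _derive_seeds(master_seed, n_restarts, stream=101)
    return min(fast_interchange(instance, seed=s)[0].objective for s in seeds)


def clustered_benchmark(
    master_seed: int, n_pipeline_runs: int = 10, n_restarts: int = 30
) -> BenchmarkResult:
    """Reassignment-only pipeline quality on a multi-cluster instance."""
    inst_seed = _derive_seeds(master_seed, 1, stream=1)[0]
    config = SyntheticConfig(
        layout="clustered",
        total_demand=600_000,
        n_gen_clusters=8,
        separation_factor=10.0,
        seed=inst_seed,
    )
    instance, _ = generate_instance(config)
    best = best_known_fi(instance, master_seed, n_restarts)
    objectives = []
    for seed in _derive_seeds(master_seed, n_pipeline_runs, stream=2):
        solution, _, _ = run_em_fi(instance, EmFiConfig(seed=seed, improve_mode="none"))
        objectives.append(solution.objective)
    rels = [relative_cost(z, best) for z in objectives]
    return BenchmarkResult(
        n=instance.n, p=instance.p, best_known=best, objectives=objectives, relative_costs=rels
    )


def centered_benchmark(
    master_seed: int, n_pipeline_runs: int = 10, n_restarts: int = 30
) -> BenchmarkResult:
    """Improvement-pipeline quality on a single-cluster instance.

    Best-known includes the improvement runs themselves alongside the
    random-restart interchange baseline.
    """
    inst_seed = _derive_seeds(master_seed, 1, stream=11)[0]
    config = SyntheticConfig(layout="centered", total_demand=450_000, seed=inst_seed)
    instance, _ = generate_instance(config)
    fi_best = best_known_fi(instance, master_seed, n_restarts)
    objectives = []
    for seed in _derive_seeds(master_seed, n_pipeline_runs, stream=12):
        solution, _, _ = run_em_fi(instance, EmFiConfig(seed=seed, improve_mode="global_fi"))
        objectives.append(solution.objective)
    best = min(fi_best, min(objectives))
    rels = [relative_cost(z, best) for z in objectives]
    return BenchmarkResult(
        n=instance.n, p=instance.p, best_known=best, objectives=objectives, relative_costs=rels
    )
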
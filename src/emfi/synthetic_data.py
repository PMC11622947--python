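"""Synthetic p-median instance generator.

Emulates the construction of census-block-group-like demand data: atomic
demand units are scattered over a fine square grid according to a chosen
spatial layout (clustered blobs, a single centered blob, or a homogeneous
uniform scatter), then merged into destinations whose sizes follow a
N(1500, 400) draw truncated below at one unit — roughly the population of a
US census block group.  The destination coordinate is the centroid of its
absorbed units and its demand weight is the absorbed unit count, so total
demand is conserved exactly.  The facility count defaults to p = round(n/4),
giving deliberately large p relative to n.

Units landing on the same grid cell are interchangeable, so aggregation is
performed on per-cell counts: a destination seeds at a random unassigned
unit and absorbs whole nearest cells (the final cell possibly partially)
until its target demand is met or units run out.  Because the scatter is
stochastic, many grid cells stay empty and unoccupied "islands" appear
naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .problem_core import DemandPoint, PMedianInstance

__all__ = ["SyntheticConfig", "scatter_demand_units", "aggregate_units_to_destinations", "generate_instance"]

LAYOUTS = ("clustered", "centered", "homogeneous")


@dataclass
class SyntheticConfig:
    """Parameters of the generator.

    cluster_spread is the per-blob standard deviation in grid-cell units;
    blob centers are rejection-sampled so every pair is at least
    ``separation_factor * cluster_spread`` apart.
    """

    layout: str = "clustered"
    grid_side: int = 256
    total_demand: int = 600_000
    n_gen_clusters: int = 8
    cluster_spread: float = 6.0
    separation_factor: float = 10.0
    demand_mean: float = 1500.0
    demand_sd: float = 400.0
    p_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"invalid config: layout must be one of {LAYOUTS}")
        if self.total_demand <= 0:
            raise ValueError("invalid config: total_demand must be > 0")
        if self.demand_mean <= 0:
            raise ValueError("invalid config: demand_mean must be > 0")
        if not (0 < self.p_fraction < 1):
            raise ValueError("invalid config: p_fraction must be in (0, 1)")
        if self.separation_factor <= 0:
            raise ValueError("invalid config: separation_factor must be > 0")


def _sample_blob_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample blob centers with the required pairwise separation."""
    margin = min(4.0 * config.cluster_spread, config.grid_side / 4)
    lo, hi = margin, config.grid_side - margin
    min_sep = config.separation_factor * config.cluster_spread
    for _ in range(200):  # restart budget
        centers: list[np.ndarray] = []
        attempts = 0
        while len(centers) < config.n_gen_clusters and attempts < 5000:
            cand = rng.uniform(lo, hi, size=2)
            attempts += 1
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
        if len(centers) == config.n_gen_clusters:
            return np.array(centers)
    raise ValueError(
        "invalid config: cannot place blob centers with the requested separation"
    )


def scatter_demand_units(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter ``total_demand`` atomic units on the grid.

    Returns integer unit positions (snapped to grid cells, clipped to the
    grid) and per-unit generator blob labels (all zero for non-clustered
    layouts).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.total_demand
    side = config.grid_side
    if config.layout == "homogeneous":
        pos = rng.integers(0, side, size=(m, 2)).astype(float)
        labels = np.zeros(m, dtype=np.intp)
    elif config.layout == "centered":
        center = np.array([side / 2, side / 2])
        spread = config.cluster_spread * 4  # one broad central blob
        pos = center + rng.normal(scale=spread, size=(m, 2))
        labels = np.zeros(m, dtype=np.intp)
    else:  # clustered: uniform mixture over well-separated Gaussian blobs
        centers = _sample_blob_centers(config, rng)
        labels = rng.integers(0, config.n_gen_clusters, size=m)
        pos = centers[labels] + rng.normal(scale=config.cluster_spread, size=(m, 2))
    pos = np.clip(np.round(pos), 0, side - 1)
    return pos.astype(float), labels


def aggregate_units_to_destinations(
    units: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    unit_labels: np.ndarray | None = None,
) -> tuple[PMedianInstance, np.ndarray]:
    """Merge demand units into destinations.

    Repeatedly: draw a target size from N(demand_mean, demand_sd) truncated
    below at 1; seed a destination at a uniformly random unassigned unit;
    absorb the nearest unassigned units (whole grid cells, the last one
    possibly partially) until the target is met or units are exhausted.
    The destination sits at the centroid of its absorbed units and weighs
    their count, so the sum of weights equals the number of units exactly.

    Returns the instance (p = round(p_fraction * n)) and the per-destination
    majority generator label.
    """
    units = np.asarray(units, dtype=float)
    if units.size == 0:
        raise ValueError("empty instance")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if unit_labels is None:
        unit_labels = np.zeros(len(units), dtype=np.intp)

    # collapse to (cell, label) groups; units within a group are identical
    keyed = np.column_stack([units, unit_labels])
    cells, counts = np.unique(keyed, axis=0, return_counts=True)
    coords = cells[:, :2]
    cell_labels = cells[:, 2].astype(np.intp)
    remaining = counts.astype(np.int64)

    dest_xy: list[np.ndarray] = []
    dest_w: list[int] = []
    dest_label: list[int] = []
    while remaining.sum() > 0:
        target = max(1, int(round(rng.normal(config.demand_mean, config.demand_sd))))
        open_idx = np.flatnonzero(remaining > 0)
        # seed at a random unassigned unit => cell chosen with prob ∝ remaining
        probs = remaining[open_idx] / remaining[open_idx].sum()
        seed_cell = rng.choice(open_idx, p=probs)
        d = np.linalg.norm(coords[open_idx] - coords[seed_cell], axis=1)
        order = open_idx[np.lexsort((open_idx, d))]
        cum = np.cumsum(remaining[order])
        k = int(np.searchsorted(cum, target))
        take_idx = order[: k + 1] if k < order.size else order
        take = remaining[take_idx].copy()
        if k < order.size:
            # absorb only what is needed from the final cell
            take[-1] -= int(cum[k] - target) if cum[k] > target else 0
        absorbed = int(take.sum())
        centroid = (coords[take_idx] * take[:, None]).sum(axis=0) / absorbed
        lbls = cell_labels[take_idx]
        label_tally = np.bincount(lbls, weights=take)
        dest_xy.append(centroid)
        dest_w.append(absorbed)
        dest_label.append(int(np.argmax(label_tally)))
        remaining[take_idx] -= take

    n = len(dest_w)
    points = [
        DemandPoint(id=f"d{i}", x=float(xy[0]), y=float(xy[1]), weight=float(w))
        for i, (xy, w) in enumerate(zip(dest_xy, dest_w))
    ]
    p = max(1, int(round(config.p_fraction * n)))
    return PMedianInstance(points, p=p), np.asarray(dest_label, dtype=np.intp)


def generate_instance(config: SyntheticConfig) -> tuple[PMedianInstance, np.ndarray]:
    """Full generator: scatter units, then aggregate into an instance.

    Returns the instance and per-destination generator blob labels (used by
    property tests on clustered layouts; all zero otherwise).
    """
    rng = np.random.default_rng(config.seed)
    units, unit_labels = scatter_demand_units(config, rng)
    return aggregate_units_to_destinations(units, config, rng, unit_labels)
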
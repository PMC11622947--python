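"""Subregion classification and merging.

A mixture component's point set is only worth an independent subproblem if
it is a genuine demand cluster: *dense* (demand per unit area above the
whole-region density) and *heterogeneous* (its points deviate significantly
from a uniform random scatter).  Non-clustered subregions — sparse or
homogeneous ones — are dissolved: each of their points joins the clustered
subregion with the nearest (pre-merge) centroid, reducing k components to q
subproblems.

Homogeneity is judged by a quadrat test: a near-square grid of N equal
cells is laid over the subregion's bounding box, and the observed frequency
F(i) of cells holding exactly i of the n_sub points is compared with the
binomial expectation E(i) = N * C(n_sub, i) p_cell^i (1-p_cell)^(n_sub-i),
p_cell = 1/N, through the statistic chi2 = sum_i (E(i)-F(i))^2 / E(i).
The statistic is referred to a chi-square distribution with n_sub degrees
of freedom; this convention is deliberately conservative (it under-rejects
uniform scatters) and is kept as the documented behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import binom, chi2 as chi2_dist

__all__ = [
    "Subregion",
    "HeterogeneityResult",
    "subregion_density",
    "heterogeneity_test",
    "classify_subregions",
    "merge_nonclustered",
    "region_demand_density",
]

DEFAULT_ALPHA = 0.05
#: expected-count tail mass below which the binomial support is truncated
_TAIL_EPS = 1e-9


@dataclass
class Subregion:
    members: np.ndarray  # point indices into the parent instance
    centroid: np.ndarray  # mean of member coordinates
    total_demand: float
    area: float
    density: float  # nan when the hull is degenerate
    is_sparse: bool = False
    is_homogeneous: bool = False

    @property
    def is_clustered(self) -> bool:
        return not self.is_sparse and not self.is_homogeneous


@dataclass
class HeterogeneityResult:
    n_sub: int
    n_cells: int
    p_cell: float
    expected: np.ndarray  # E(i), truncated support with tail mass folded in
    observed: np.ndarray  # F(i), same support
    chi2: float
    dof: int
    p_value: float
    reject: bool


def _hull_area(coords: np.ndarray) -> float:
    """Convex-hull area; 0 for degenerate geometry (< 3 points, collinear)."""
    pts = np.unique(coords, axis=0)
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # "volume" is area in 2-D
    except QhullError:
        return 0.0


def subregion_density(
    subregion_points: np.ndarray, weights: np.ndarray
) -> tuple[float, float, float]:
    """Total demand, convex-hull area and demand density of a point group.

    Density is demand per unit area; degenerate hulls (area 0) yield
    density nan and are treated as sparse by the classifier.
    """
    coords = np.asarray(subregion_points, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty subregion")
    total = float(np.sum(weights))
    area = _hull_area(coords)
    density = total / area if area > 0 else float("nan")
    return total, area, density


def region_demand_density(coords: np.ndarray, weights: np.ndarray) -> float:
    """Demand density of the whole region (hull of all points)."""
    total, area, density = subregion_density(coords, weights)
    if area <= 0:
        raise ValueError("degenerate region geometry")
    return density


def _grid_shape(n_cells: int) -> tuple[int, int]:
    """Near-square rows x cols factorisation covering at least n_cells."""
    rows = max(1, int(round(np.sqrt(n_cells))))
    cols = int(np.ceil(n_cells / rows))
    return rows, cols


def heterogeneity_test(
    member_coords: np.ndarray,
    n_cells: int | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> HeterogeneityResult:
    """Quadrat chi-square test of spatial homogeneity.

    ``n_cells`` defaults to max(9, ceil(n_sub / 8)) — an average occupancy
    of about eight points per cell, coarse enough that expected counts per
    occupancy bin are non-negligible; with the conservative dof = n_sub
    convention a finer grid has essentially no power against smooth density
    gradients.  The requested count is rounded up to a near-square
    rows x cols grid.
    The binomial support is truncated where the remaining expected mass
    falls below 1e-9, with the residual folded into the last bin so that
    sum(E) = N holds exactly; observed counts beyond the truncation point
    fold into the same bin.
    """
    coords = np.asarray(member_coords, dtype=float)
    n_sub = coords.shape[0]
    if n_sub == 0:
        raise ValueError("empty subregion")
    if n_cells is None:
        n_cells = max(9, int(np.ceil(n_sub / 8)))
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rows, cols = _grid_shape(n_cells)
    n = rows * cols  # actual cell count N
    p_cell = 1.0 / n

    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span[span == 0] = 1.0
    cx = np.minimum((coords[:, 0] - lo[0]) / span[0] * cols, cols - 1).astype(int)
    cy = np.minimum((coords[:, 1] - lo[1]) / span[1] * rows, rows - 1).astype(int)
    occupancy = np.bincount(cy * cols + cx, minlength=n)
    per_count = np.bincount(occupancy, minlength=n_sub + 1)  # F(i), i = 0..n_sub

    # truncate the support where the cumulative expected tail is negligible
    pmf = binom.pmf(np.arange(n_sub + 1), n_sub, p_cell)
    sf = 1.0 - np.cumsum(pmf)
    cut = int(np.searchsorted(n * sf < _TAIL_EPS, True))
    cut = min(cut, n_sub)
    expected = n * pmf[: cut + 1]
    expected[-1] += n * max(sf[cut], 0.0)  # fold residual mass: sum(E) = N
    observed = per_count[: cut + 1].astype(float)
    observed[-1] += per_count[cut + 1 :].sum()

    stat = float(np.sum((expected - observed) ** 2 / expected))
    dof = n_sub
    p_value = float(chi2_dist.sf(stat, dof))
    return HeterogeneityResult(
        n_sub=n_sub,
        n_cells=n,
        p_cell=p_cell,
        expected=expected,
        observed=observed,
        chi2=stat,
        dof=dof,
        p_value=p_value,
        reject=bool(p_value < alpha),
    )


def build_subregions(coords: np.ndarray, weights: np.ndarray, labels: np.ndarray) -> list[Subregion]:
    """Group points by component label into Subregion records."""
    subregions = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        total, area, density = subregion_density(coords[members], weights[members])
        subregions.append(
            Subregion(
                members=members,
                centroid=coords[members].mean(axis=0),
                total_demand=total,
                area=area,
                density=density,
            )
        )
    return subregions


def classify_subregions(
    subregions: list[Subregion],
    coords: np.ndarray,
    region_density: float,
    alpha: float = DEFAULT_ALPHA,
    n_cells: int | None = None,
) -> list[Subregion]:
    """Set the sparse/homogeneous flags on every subregion (in place).

    Sparse: demand density strictly below the whole-region density (a
    degenerate-hull subregion is always sparse).  Homogeneous: the quadrat
    test fails to reject uniform scatter.
    """
    if region_density <= 0:
        raise ValueError("region_density must be > 0")
    for sub in subregions:
        sub.is_sparse = (not np.isfinite(sub.density)) or sub.density < region_density
        result = heterogeneity_test(coords[sub.members], n_cells=n_cells, alpha=alpha)
        sub.is_homogeneous = not result.reject
    return subregions


def merge_nonclustered(
    subregions: list[Subregion], coords: np.ndarray, weights: np.ndarray
) -> list[Subregion]:
    """Dissolve non-clustered subregions into the clustered ones.

    Every point of a sparse or homogeneous subregion joins the clustered
    subregion whose pre-merge centroid is nearest (ties: lowest subregion
    index).  Raises when no subregion is clustered — the fully homogeneous
    case, which callers handle by not decomposing at all.
    """
    clustered = [s for s in subregions if s.is_clustered]
    if not clustered:
        raise ValueError("fully homogeneous region: no clustered subregion")
    if len(clustered) == len(subregions):
        return subregions
    centroids = np.array([s.centroid for s in clustered])
    new_members: list[list[int]] = [list(s.members) for s in clustered]
    for s in subregions:
        if s.is_clustered:
            continue
        d = np.linalg.norm(coords[s.members][:, None, :] - centroids[None, :, :], axis=2)
        target = np.argmin(d, axis=1)
        for point, t in zip(s.members, target):
            new_members[t].append(int(point))
    merged = []
    for s, members in zip(clustered, new_members):
        idx = np.sort(np.asarray(members, dtype=np.intp))
        total, area, density = subregion_density(coords[idx], weights[idx])
        merged.append(
            Subregion(
                members=idx,
                centroid=coords[idx].mean(axis=0),
                total_demand=total,
                area=area,
                density=density,
                is_sparse=s.is_sparse,
                is_homogeneous=s.is_homogeneous,
            )
        )
    return merged
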
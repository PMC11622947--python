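"""Density-based decomposition by Gaussian mixture modelling.

Demand-point coordinates are modelled as a c-component bivariate Gaussian
mixture

    p(x) = sum_{i=1..c} theta_i * N(x | mu_i, Sigma_i),

fitted by expectation-maximization for every c in 2..c_max.  Each fitted
model is scored by the Bayesian information criterion

    BIC = ln(n) * c_m - 2 * ln(L_hat),

with c_m = 6c - 1 free parameters for full bivariate covariances (c - 1
mixture weights, 2c mean entries, 3c covariance entries); the minimum-BIC
model wins and its maximum-posterior component labels define the candidate
subregions.  Mixture weights are deliberately fitted on coordinates only —
demand weights enter later through subregion densities and facility
apportionment.

The EM fits themselves are delegated to scikit-learn's GaussianMixture;
the BIC accounting and the model-selection sweep are owned here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "GmmModel",
    "ComponentLabeling",
    "fit_gmm",
    "bic_score",
    "select_component_model",
    "label_points",
]

DEFAULT_CMAX = 20
EM_TOL = 1e-4
EM_MAX_ITER = 200
EM_N_INIT = 5
COV_RIDGE = 1e-6


@dataclass
class GmmModel:
    """A fitted c-component bivariate Gaussian mixture."""

    c: int
    weights: np.ndarray  # theta, shape (c,)
    means: np.ndarray  # shape (c, 2)
    covariances: np.ndarray  # shape (c, 2, 2)
    log_likelihood: float  # total ln L_hat over the fitted sample
    parameter_count: int  # 6c - 1
    bic: float
    _sk: GaussianMixture | None = None


@dataclass
class ComponentLabeling:
    labels: np.ndarray  # argmax-responsibility component per point, 0-based
    responsibilities: np.ndarray  # shape (n, c), rows sum to 1


def bic_score(log_likelihood: float, n: int, c: int) -> float:
    """BIC of a c-component full-covariance bivariate mixture."""
    if n < 1:
        raise ValueError("invalid n")
    c_m = 6 * c - 1
    return float(np.log(n) * c_m - 2.0 * log_likelihood)


def fit_gmm(points: np.ndarray, c: int, seed: int | None = None) -> GmmModel:
    """Fit a c-component mixture by EM with k-means++ starts and restarts."""
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = x.shape[0]
    if c < 1 or n < c:
        raise ValueError("degenerate mixture: need n >= c >= 1")
    if np.unique(x, axis=0).shape[0] < c:
        raise ValueError("degenerate mixture: fewer distinct points than components")
    gm = GaussianMixture(
        n_components=c,
        covariance_type="full",
        tol=EM_TOL,
        max_iter=EM_MAX_ITER,
        n_init=EM_N_INIT,
        init_params="k-means++",
        reg_covar=COV_RIDGE,
        random_state=seed,
    )
    gm.fit(x)
    ll = float(gm.score(x) * n)
    return GmmModel(
        c=c,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        log_likelihood=ll,
        parameter_count=6 * c - 1,
        bic=bic_score(ll, n, c),
        _sk=gm,
    )


def label_points(model: GmmModel, points: np.ndarray) -> ComponentLabeling:
    """Maximum-posterior component membership with full responsibilities."""
    x = np.asarray(points, dtype=float)
    if model._sk is not None:
        resp = model._sk.predict_proba(x)
    else:  # model rebuilt from parameters: compute responsibilities directly
        from scipy.stats import multivariate_normal

        dens = np.column_stack(
            [
                model.weights[i]
                * multivariate_normal.pdf(x, model.means[i], model.covariances[i])
                for i in range(model.c)
            ]
        )
        resp = dens / dens.sum(axis=1, keepdims=True)
    return ComponentLabeling(labels=np.argmax(resp, axis=1), responsibilities=resp)


def select_component_model(
    points: np.ndarray, c_max: int = DEFAULT_CMAX, seed: int | None = None
) -> tuple[GmmModel, ComponentLabeling, int]:
    """Sweep c = 2..c_max, return the minimum-BIC model and its labeling.

    c is additionally capped at the number of distinct coordinates.  Raises
    when no component count can be fitted ("decomposition failed"); callers
    fall back to an undecomposed solve.
    """
    x = np.asarray(points, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("decomposition failed: need at least 2 points")
    c_cap = min(c_max, np.unique(x, axis=0).shape[0], n)
    ss = np.random.SeedSequence(seed)
    best: GmmModel | None = None
    for c, child in zip(range(2, c_cap + 1), ss.spawn(max(0, c_cap - 1))):
        try:
            model = fit_gmm(x, c, seed=int(child.generate_state(1)[0] % (2**31)))
        except (ValueError, np.linalg.LinAlgError):
            continue
        if best is None or model.bic < best.bic:
            best = model
    if best is None:
        raise ValueError("decomposition failed: no mixture could be fitted")
    return best, label_points(best, x), best.c
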
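"""Spatial pattern analyses: geographic distance, distance-decay and MRM.

Distance-decay fits community dissimilarity against great-circle distance
with a log-link Gaussian GLM (exponential decay family); significance comes
from permutations of the dissimilarity matrix.  Multiple regression on
distance matrices (MRM) regresses the unfolded lower triangle of a response
distance matrix on one or more predictor matrices, with significance by
simultaneous row/column permutation of the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from skbio import DistanceMatrix

from .containers import SampleMetadata

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "DecayFit",
    "MRMResult",
    "haversine_km",
    "geographic_distances",
    "distance_decay",
    "mrm",
]


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distances(metadata: SampleMetadata) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between sample stations."""
    coords = metadata.coordinates().to_numpy()
    n = len(coords)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = haversine_km(*coords[i], *coords[j])
    return DistanceMatrix(D, ids=metadata.sample_ids)


def _lower_triangle(dm: DistanceMatrix, order: list[str]) -> np.ndarray:
    idx = [dm.index(i) for i in order]
    M = dm.data[np.ix_(idx, idx)]
    n = M.shape[0]
    return M[np.tril_indices(n, -1)]


@dataclass
class DecayFit:
    """Exponential distance-decay fit of dissimilarity vs distance."""

    model: str                 # 'dissimilarity' or 'similarity'
    intercept: float
    slope_per_km: float
    pseudo_r2: float
    p_value: float
    n_perm: int


def _glm_log(y: np.ndarray, x: np.ndarray):
    X = sm.add_constant(x)
    fam = sm.families.Gaussian(link=sm.families.links.Log())
    return sm.GLM(y, X, family=fam).fit()


def distance_decay(
    d_comm: DistanceMatrix,
    d_geo_km: DistanceMatrix,
    model: str = "dissimilarity",
    n_perm: int = 999,
    seed: int = 0,
) -> DecayFit:
    """Fit y = exp(a + b * distance_km) to pairwise community (dis)similarity.

    ``model='similarity'`` fits 1 - dissimilarity instead.  The p-value
    permutes sample identities of the community matrix (rows and columns
    together) and compares the magnitude of the refit slope.
    """
    order = list(d_comm.ids)
    if set(order) != set(d_geo_km.ids):
        raise ValueError("community and geographic matrices must share labels")
    x = _lower_triangle(d_geo_km, order)
    y_raw = _lower_triangle(d_comm, order)
    y = 1.0 - y_raw if model == "similarity" else y_raw
    if np.allclose(y, y[0]):
        raise ValueError("constant response; decay model is degenerate")
    if np.allclose(x, x[0]):
        raise ValueError("constant geographic distances")
    eps = 1e-12
    res = _glm_log(np.maximum(y, eps), x)
    a, b = float(res.params[0]), float(res.params[1])
    null_dev = float(res.null_deviance)
    pseudo_r2 = 1.0 - float(res.deviance) / null_dev if null_dev > 0 else 0.0

    rng = np.random.default_rng(seed)
    n = len(order)
    M = d_comm.data
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Mp = M[np.ix_(perm, perm)]
        yp = Mp[np.tril_indices(n, -1)]
        if model == "similarity":
            yp = 1.0 - yp
        bp = float(_glm_log(np.maximum(yp, eps), x).params[1])
        if abs(bp) >= abs(b):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return DecayFit(model, a, b, float(pseudo_r2), float(p), n_perm)


@dataclass
class MRMResult:
    r2: float
    f_statistic: float
    f_p_value: float
    coefficients: pd.Series
    coef_p_values: pd.Series
    n_perm: int


def _ols_stats(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float, np.ndarray]:
    """(beta, R2, F, t-stats) for OLS with intercept column already in X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("collinear predictors (singular fit)")
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = X.shape
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    df_res = n - p
    if p <= 1:
        f = np.nan
    elif r2 >= 1.0:
        f = np.inf
    else:
        f = (r2 / (p - 1)) / ((1 - r2) / df_res)
    sigma2 = ss_res / df_res
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    return beta, r2, float(f), beta / se


def mrm(
    response: DistanceMatrix,
    *predictors: DistanceMatrix,
    names: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> MRMResult:
    """Multiple regression on distance matrices with permutation tests.

    OLS on unfolded lower triangles; p-values permute the response matrix's
    rows and columns simultaneously.  The overall test uses F, each
    coefficient its pseudo-t magnitude.
    """
    if not predictors:
        raise ValueError("need at least one predictor matrix")
    order = list(response.ids)
    for p_dm in predictors:
        if set(p_dm.ids) != set(order):
            raise ValueError("all matrices must share labels")
    y = _lower_triangle(response, order)
    Xcols = [_lower_triangle(p_dm, order) for p_dm in predictors]
    X = np.column_stack([np.ones_like(y), *Xcols])
    names = names or [f"X{i + 1}" for i in range(len(predictors))]
    beta, r2, f_obs, t_obs = _ols_stats(y, X)

    rng = np.random.default_rng(seed)
    n = len(order)
    M = response.data
    f_count = 0
    t_counts = np.zeros(len(beta))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = M[np.ix_(perm, perm)][np.tril_indices(n, -1)]
        _, _, f_p, t_p = _ols_stats(yp, X)
        if f_p >= f_obs:
            f_count += 1
        t_counts += np.abs(t_p) >= np.abs(t_obs)
    f_pval = (1 + f_count) / (1 + n_perm)
    coef_p = (1 + t_counts) / (1 + n_perm)
    idx = ["intercept"] + list(names)
    return MRMResult(
        float(r2), float(f_obs), float(f_pval),
        pd.Series(beta, index=idx),
        pd.Series(coef_p, index=idx),
        n_perm,
    )
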
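"""Population structure: genotype PCA and IBD/IBE regression on distances.

Isolation by distance vs. isolation by environment is tested by multiple
regression on distance matrices (MRM): ordinary least squares on the
vectorized lower triangles of a genetic-distance response (pairwise
multi-locus FST) against geographic (great-circle km) and environmental
(Euclidean over z-scored predictors) distance matrices, with significance
from Mantel-style joint row/column permutation of the response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, wc_fst

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceSet:
    """Aligned site x site distance matrices (genetic, geographic, environmental)."""

    sites: list[str]
    genetic: np.ndarray
    geographic: np.ndarray
    environmental: np.ndarray

    def __post_init__(self) -> None:
        for name in ("genetic", "geographic", "environmental"):
            m = getattr(self, name)
            if m.shape != (len(self.sites), len(self.sites)):
                raise ValueError(f"{name} matrix shape does not match site list")
            if not np.allclose(m, m.T, equal_nan=True):
                raise ValueError(f"{name} matrix is not symmetric")


@dataclass
class MRMResult:
    """MRM coefficients with permutation p-values."""

    predictors: list[str]
    beta: np.ndarray            # slope per predictor matrix
    intercept: float
    r2: float
    p_perm: np.ndarray          # per-coefficient two-sided permutation p
    p_r2: float


# ---------------------------------------------------------------------------

def pca_genotypes(gm: GenotypeMatrix, n_axes: int = 10):
    """PCA of the genotype matrix under Patterson normalisation.

    Loci are centered by their mean dosage ``2 p-hat`` and scaled by
    ``sqrt(2 p-hat (1 - p-hat))``; monomorphic loci are dropped; missing
    genotypes are mean-imputed.  Axis signs are canonicalized so that the
    largest-|loading| locus on each axis loads positively.

    Returns (scores ``(n_samples, n_axes)``, variance fractions).
    """
    G = gm.G.astype(float)
    G[gm.G == -1] = np.nan
    col_mean = np.nanmean(G, axis=0)
    p_hat = col_mean / 2.0
    poly = (p_hat > 0) & (p_hat < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic: PCA undefined")
    G = G[:, poly]
    col_mean = col_mean[poly]
    p_hat = p_hat[poly]
    inds = np.where(np.isnan(G))
    G[inds] = col_mean[inds[1]]
    X = (G - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))

    n_axes = min(n_axes, min(X.shape) - 1) if min(X.shape) > 1 else 1
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float((s ** 2).sum())
    scores = U[:, :n_axes] * s[:n_axes]
    var_frac = (s[:n_axes] ** 2) / total_var
    for k in range(n_axes):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] *= -1
    return scores, var_frac


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * radius * np.arcsin(np.sqrt(np.clip(h, 0, 1))))


def distance_matrices(coords: pd.DataFrame, env: pd.DataFrame,
                      gm: GenotypeMatrix, predictors: list[str]) -> DistanceSet:
    """Build the aligned genetic / geographic / environmental distance set.

    ``coords`` needs columns ``lat``/``lon`` indexed by site (deme) label;
    ``env`` holds predictor columns on the same index.  Genetic distance is
    pairwise multi-locus Weir-Cockerham FST between demes of ``gm``; sites
    with fewer than two samples are excluded with a warning.
    """
    demes = np.asarray(gm.demes)
    sites = [s for s in coords.index if s in set(demes)]
    counts = {s: int((demes == s).sum()) for s in sites}
    small = [s for s in sites if counts[s] < 2]
    if small:
        logger.warning("distance_matrices: excluding sites with <2 samples: %s", small)
        sites = [s for s in sites if counts[s] >= 2]
    if len(sites) < 3:
        raise ValueError("need at least 3 usable sites")

    k = len(sites)
    geo = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = haversine_km(coords.loc[sites[i], "lat"], coords.loc[sites[i], "lon"],
                             coords.loc[sites[j], "lat"], coords.loc[sites[j], "lon"])
            geo[i, j] = geo[j, i] = d

    Z = env.loc[sites, predictors].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    diff = Z[:, None, :] - Z[None, :, :]
    envd = np.sqrt((diff ** 2).sum(axis=2))

    gen = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = gm.subset_samples(np.isin(demes, [sites[i], sites[j]]))
            _, multi = wc_fst(sub, [sites[i], sites[j]])
            gen[i, j] = gen[j, i] = multi
    return DistanceSet(sites, gen, geo, envd)


# ---------------------------------------------------------------------------

def _lower_triangle(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mrm(response: np.ndarray, predictors: dict[str, np.ndarray],
        n_perm: int = 999, seed: int = 0) -> MRMResult:
    """Multiple regression on distance matrices with permutation inference.

    OLS of the vectorized lower triangle of ``response`` on those of the
    predictor matrices; p-values from ``n_perm`` Mantel-style joint
    row/column permutations of the response matrix, with the add-one
    rule p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    names = list(predictors)
    k = response.shape[0]
    X_cols = []
    for name in names:
        m = predictors[name]
        if m.shape != response.shape:
            raise ValueError(f"predictor {name!r} not conformable with response")
        v = _lower_triangle(m)
        if np.allclose(v, v[0]):
            raise ValueError(f"predictor matrix {name!r} is constant: coefficient undefined")
        X_cols.append(v)
    X = np.column_stack([np.ones(k * (k - 1) // 2)] + X_cols)
    y = _lower_triangle(response)

    H = np.linalg.pinv(X)                       # (p+1, q)
    coef = H @ y
    fitted = X @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(((y - fitted) ** 2).sum()) / sst if sst > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    exceed_r2 = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = _lower_triangle(response[np.ix_(perm, perm)])
        cp = H @ yp
        fp = X @ cp
        sstp = float(((yp - yp.mean()) ** 2).sum())
        r2p = 1.0 - float(((yp - fp) ** 2).sum()) / sstp if sstp > 0 else 0.0
        exceed += np.abs(cp[1:]) >= np.abs(coef[1:])
        exceed_r2 += r2p >= r2
    p_perm = (1.0 + exceed) / (n_perm + 1.0)
    p_r2 = (1.0 + exceed_r2) / (n_perm + 1.0)
    return MRMResult(names, coef[1:], float(coef[0]), r2, p_perm, float(p_r2))
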
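"""Habitat suitability ensemble and landscape resistance surface.

The suitability model is a deliberately minimal presence/background
ensemble: collinearity screening by iterative VIF filtering, repeated
70/30 split evaluation scored by ROC-AUC and the True Skill Statistic
(TSS = sensitivity + specificity - 1, maximized over a threshold grid),
and a TSS-weighted mean of member predictions from which members scoring
TSS <= 0.60 are excluded.

The resistance surface encodes hypothesized difficulty of movement on a
1 (lowest) to 10 (highest) scale: per terrain feature (elevation, local
elevation SD, slope) the absolute deviation of each cell from the mean
over currently occupied cells, min-max normalized, averaged with inverted
habitat suitability, and linearly rescaled to [1, 10].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .raster import RasterGrid, check_conformable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Collinearity screen

def vif_values(env: pd.DataFrame) -> dict[str, float]:
    """VIF per predictor: 1/(1-R^2) from regressing each on all others."""
    cols = list(env.columns)
    X = env.to_numpy(dtype=float)
    out: dict[str, float] = {}
    for j, name in enumerate(cols):
        others = [k for k in range(len(cols)) if k != j]
        A = np.column_stack([np.ones(len(X))] + [X[:, k] for k in others])
        y = X[:, j]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 0.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(env: pd.DataFrame, threshold: float = 2.5) -> list[str]:
    """Iteratively drop the predictor with the largest VIF until all <= threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others.
    Perfectly collinear predictors have infinite VIF; among ties the
    predictor with the larger column index is dropped first.
    """
    cols = list(env.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 predictors")
    if len(env) <= len(cols):
        raise ValueError("need more rows than predictors")
    keep = list(cols)
    while len(keep) > 1:
        vifs = np.array([vif_values(env[keep])[c] for c in keep])
        if np.nanmax(vifs) <= threshold:
            break
        # argmax over reversed order drops the larger index among ties
        worst_pos = len(vifs) - 1 - int(np.argmax(vifs[::-1]))
        keep.pop(worst_pos)
    return keep


# ---------------------------------------------------------------------------
# Model evaluation

def evaluate_model(scores: np.ndarray, labels: np.ndarray,
                   threshold_grid: np.ndarray | None = None):
    """TSS (maximized over thresholds), ROC-AUC and the best threshold.

    ``labels`` are 1 = presence, 0 = background; ``scores`` are predicted
    suitabilities.  Raises if the test set contains a single class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("test set contains a single class")
    if threshold_grid is None:
        threshold_grid = np.linspace(0.0, 1.0, 101)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    best_tss, best_thr = -np.inf, threshold_grid[0]
    for thr in threshold_grid:
        pred = scores >= thr
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss:
            best_tss, best_thr = tss, float(thr)
    auc = float(roc_auc_score(labels, scores))
    return float(best_tss), auc, best_thr


# ---------------------------------------------------------------------------
# Ensemble

def default_learners(seed: int = 0):
    """The two ensemble members: linear-logistic and tree-ensemble."""
    return [
        ("logistic", LogisticRegression(max_iter=1000)),
        ("forest", RandomForestClassifier(n_estimators=200, random_state=seed,
                                          n_jobs=1)),
    ]


@dataclass
class SDMEnsemble:
    """TSS-weighted suitability ensemble over a raster landscape."""

    member_scores: dict[str, dict[str, float]]   # name -> {tss, auc, threshold}
    weights: dict[str, float]                    # 0 for excluded members
    suitability: RasterGrid
    tss_threshold: float
    best_threshold: float                        # TSS-maximizing binarization cut

    def report(self) -> dict:
        return {"members": self.member_scores, "weights": self.weights,
                "tss_threshold": self.tss_threshold,
                "best_threshold": self.best_threshold}


def _features_at(layers: dict[str, RasterGrid], cells: np.ndarray,
                 names: list[str]) -> np.ndarray:
    return np.column_stack([layers[v].data[cells[:, 0], cells[:, 1]] for v in names])


def fit_ensemble(layers: dict[str, RasterGrid], occurrences: np.ndarray,
                 background_n: int = 1000, learners=None, n_repeats: int = 3,
                 test_fraction: float = 0.30, tss_threshold: float = 0.60,
                 seed: int = 0) -> SDMEnsemble:
    """Fit the presence/background ensemble and predict over the grid.

    Per learner and repeat, a random 70/30 presence+background split is
    fit/evaluated; a learner's TSS is its mean over repeats.  Members
    with TSS <= ``tss_threshold`` get weight 0; the ensemble suitability
    is the TSS-weighted mean of member probability surfaces.  Raises with
    the scores if no member passes.
    """
    occurrences = np.asarray(occurrences)
    if len(occurrences) < 20:
        raise ValueError("need >= 20 occurrence records")
    names = sorted(layers)
    check_conformable(*[layers[v] for v in names])
    shape = layers[names[0]].shape
    rng = np.random.default_rng(seed)

    bg_flat = rng.choice(shape[0] * shape[1], size=background_n, replace=True)
    background = np.column_stack(np.unravel_index(bg_flat, shape))
    X = np.vstack([_features_at(layers, occurrences, names),
                   _features_at(layers, background, names)])
    y = np.concatenate([np.ones(len(occurrences), dtype=int),
                        np.zeros(len(background), dtype=int)])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd

    if learners is None:
        learners = default_learners(seed)

    scores: dict[str, dict[str, float]] = {}
    for name, model in learners:
        tss_list, auc_list, thr_list = [], [], []
        for rep in range(n_repeats):
            rs = np.random.default_rng([seed, rep, 7]).permutation(len(y))
            n_test = int(round(test_fraction * len(y)))
            test, train = rs[:n_test], rs[n_test:]
            if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
                continue
            model.fit(Xs[train], y[train])
            prob = model.predict_proba(Xs[test])[:, 1]
            tss, auc, thr = evaluate_model(prob, y[test])
            tss_list.append(tss)
            auc_list.append(auc)
            thr_list.append(thr)
        scores[name] = {"tss": float(np.mean(tss_list)) if tss_list else -1.0,
                        "auc": float(np.mean(auc_list)) if auc_list else 0.5,
                        "threshold": float(np.mean(thr_list)) if thr_list else 0.5}

    passing = {n: s["tss"] for n, s in scores.items() if s["tss"] > tss_threshold}
    if not passing:
        raise ValueError(f"no ensemble member exceeds TSS {tss_threshold}: {scores}")
    wsum = sum(passing.values())
    weights = {n: (passing.get(n, 0.0) / wsum) for n in scores}

    # refit passing members on all data and predict the whole grid
    grid_cells = np.column_stack(np.unravel_index(
        np.arange(shape[0] * shape[1]), shape))
    Xg = (_features_at(layers, grid_cells, names) - mu) / sd
    surface = np.zeros(shape[0] * shape[1])
    for name, model in learners:
        if weights[name] == 0.0:
            continue
        model.fit(Xs, y)
        surface += weights[name] * model.predict_proba(Xg)[:, 1]
    suit = RasterGrid(surface.reshape(shape),
                      layers[names[0]].cellsize,
                      layers[names[0]].xllcorner, layers[names[0]].yllcorner)
    best_thr = float(np.average(
        [scores[n]["threshold"] for n in passing],
        weights=[passing[n] for n in passing]))
    return SDMEnsemble(scores, weights, suit, tss_threshold, best_thr)


# ---------------------------------------------------------------------------
# Resistance surface

def elevation_sd(elev: RasterGrid, window: int = 3) -> RasterGrid:
    """Local standard deviation of elevation (moving window)."""
    x = elev.data
    m = uniform_filter(x, size=window, mode="reflect")
    m2 = uniform_filter(x * x, size=window, mode="reflect")
    return elev.copy_with(np.sqrt(np.maximum(m2 - m * m, 0.0)))


@dataclass
class ResistanceSurface:
    grid: RasterGrid                  # values in [1, 10]
    provenance: list[str]


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def resistance_surface(features: dict[str, RasterGrid], suitability: RasterGrid,
                       occupied: np.ndarray) -> ResistanceSurface:
    """Deviation-from-occupied-mean resistance on a 1-10 scale.

    For each terrain feature: the absolute difference between each cell
    and the feature's mean over occupied cells, min-max normalized to
    [0, 1].  Habitat suitability enters inverted (max suitability minus
    cell value), likewise normalized.  The equal-weight average of these
    components is rescaled linearly to [1, 10]; a constant combined
    surface degenerates to all-1 with a warning.
    """
    occupied = np.asarray(occupied)
    if occupied.size == 0:
        raise ValueError("occupied cell set is empty")
    check_conformable(*features.values(), suitability)
    comps = []
    names = sorted(features)
    for name in names:
        f = features[name].data
        m = float(np.nanmean(f[occupied[:, 0], occupied[:, 1]]))
        comps.append(_minmax(np.abs(f - m)))
    comps.append(_minmax(np.nanmax(suitability.data) - suitability.data))
    combined = np.mean(comps, axis=0)
    rng_ = np.nanmax(combined) - np.nanmin(combined)
    if rng_ <= 0:
        logger.warning("resistance_surface: degenerate constant surface, all cells = 1")
        out = np.ones_like(combined)
    else:
        out = 1.0 + 9.0 * (combined - np.nanmin(combined)) / rng_
    return ResistanceSurface(suitability.copy_with(out), names + ["suitability"])


def suitable_fraction(suitability: RasterGrid, threshold: float,
                      regions: np.ndarray | None = None) -> dict[str, float]:
    """Fraction of cells with suitability >= threshold, per region and overall."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    vals = suitability.data
    out = {"overall": float(np.nanmean(vals >= threshold))}
    if regions is not None:
        regions = np.asarray(regions)
        for lab in pd.unique(regions.ravel()):
            if lab in ("", None):
                continue
            out[str(lab)] = float(np.nanmean(vals[regions == lab] >= threshold))
    return out
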
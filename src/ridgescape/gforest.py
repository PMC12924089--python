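"""Gradient-forest turnover modelling and genomic offset.

For every locus in a panel, a regression forest predicts its per-site
allele frequency from the environmental predictors.  Each split in each
tree contributes its impurity reduction at the split threshold; per locus
these contributions are normalized to unit mass and weighted by the
forest's out-of-bag R^2 (truncated at zero).  Accumulated over loci and
sorted along each predictor's gradient they form the predictor's
*cumulative importance* (turnover) function: a monotone, right-continuous
step function F with F(min) = 0 and F(max) = the predictor's overall
importance.

Mapping every raster cell's climate through these functions yields a
"genomic composition" vector per cell; the *genomic offset* of a future
scenario is the Euclidean distance between future and current
compositions, cell by cell.  Values outside the fitted climate range are
clamped to the range endpoints (the step functions are flat there by
construction).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from statsmodels.stats.multitest import multipletests

from .raster import RasterGrid, check_conformable

logger = logging.getLogger(__name__)


@dataclass
class TurnoverModel:
    """Fitted turnover functions: one monotone step function per predictor."""

    predictors: list[str]
    breakpoints: dict[str, np.ndarray]    # sorted split thresholds
    masses: dict[str, np.ndarray]         # importance mass at each threshold
    env_range: dict[str, tuple[float, float]]
    n_trees: int
    n_loci_used: int
    seed: int

    @property
    def importance(self) -> dict[str, float]:
        """Overall R^2-weighted importance per predictor (= F(max))."""
        return {v: float(self.masses[v].sum()) for v in self.predictors}

    def cumulative_importance(self, predictor: str, x) -> np.ndarray:
        """Evaluate the turnover function F_v at values ``x`` (clamped)."""
        if predictor not in self.breakpoints:
            raise KeyError(f"no turnover function for predictor {predictor!r}")
        lo, hi = self.env_range[predictor]
        xv = np.clip(np.asarray(x, dtype=float), lo, hi)
        bp = self.breakpoints[predictor]
        cum = np.concatenate([[0.0], np.cumsum(self.masses[predictor])])
        return cum[np.searchsorted(bp, xv, side="right")]

    def to_json(self, path) -> None:
        obj = {
            "predictors": self.predictors,
            "breakpoints": {v: self.breakpoints[v].tolist() for v in self.predictors},
            "masses": {v: self.masses[v].tolist() for v in self.predictors},
            "env_range": {v: list(self.env_range[v]) for v in self.predictors},
            "n_trees": self.n_trees, "n_loci_used": self.n_loci_used,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TurnoverModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["predictors"],
            {v: np.asarray(d["breakpoints"][v]) for v in d["predictors"]},
            {v: np.asarray(d["masses"][v]) for v in d["predictors"]},
            {v: tuple(d["env_range"][v]) for v in d["predictors"]},
            d["n_trees"], d["n_loci_used"], d["seed"])


@dataclass
class OffsetSurface:
    """Genomic offset raster for one climate scenario."""

    grid: RasterGrid
    scenario: str = ""
    ssp: str = ""
    period: str = ""
    gcm: str = ""


# ---------------------------------------------------------------------------
# Fitting

def _tree_split_improvements(tree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(feature, threshold, impurity reduction) for every internal node."""
    t = tree.tree_
    internal = t.children_left != -1
    w = t.weighted_n_node_samples
    imp = t.impurity
    left, right = t.children_left[internal], t.children_right[internal]
    gain = (w[internal] * imp[internal]
            - w[left] * imp[left] - w[right] * imp[right])
    return t.feature[internal], t.threshold[internal], np.maximum(gain, 0.0)


def fit_turnover(freqs: pd.DataFrame, env: pd.DataFrame,
                 n_trees: int = 500, mtry: int | None = None,
                 seed: int = 0, max_loci: int | None = None) -> TurnoverModel:
    """Fit per-locus regression forests and accumulate turnover functions.

    Parameters
    ----------
    freqs:
        Sites x loci allele frequencies (or dosages); one column per locus.
    env:
        Sites x predictors table, same row order as ``freqs``.
    n_trees, mtry:
        Forest size and per-split feature draw (default ceil(p/3)).
    max_loci:
        Optional cap: a seeded subsample of loci for large panels.
    """
    if len(freqs) != len(env):
        raise ValueError("freqs and env must cover the same sites")
    if len(freqs) < 8:
        raise ValueError("need >= 8 sites to fit turnover functions")
    # canonical site order: the fit must not depend on row permutation
    env = env.loc[freqs.index] if not freqs.index.equals(env.index) else env
    order = np.argsort(freqs.index)
    freqs = freqs.iloc[order]
    env = env.iloc[order]
    predictors = list(env.columns)
    X = env.to_numpy(dtype=float)
    p = X.shape[1]
    mtry = mtry if mtry is not None else int(np.ceil(p / 3))

    cols = list(freqs.columns)
    rng = np.random.default_rng(seed)
    if max_loci is not None and len(cols) > max_loci:
        keep = rng.choice(len(cols), size=max_loci, replace=False)
        cols = [cols[i] for i in sorted(keep)]

    informative = [c for c in cols if freqs[c].std() > 0]
    if not informative:
        raise ValueError("no informative loci: all responses constant")

    bp: dict[str, list[float]] = {v: [] for v in predictors}
    ms: dict[str, list[float]] = {v: [] for v in predictors}
    n_used = 0
    for li, c in enumerate(informative):
        y = freqs[c].to_numpy(dtype=float)
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=mtry, bootstrap=True,
            oob_score=True, random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # few-sample OOB warnings
            forest.fit(X, y)
        r2 = max(float(getattr(forest, "oob_score_", 0.0)), 0.0)
        if r2 <= 0:
            continue
        n_used += 1
        feats, thrs, gains = [], [], []
        for est in forest.estimators_:
            f, t, g = _tree_split_improvements(est)
            feats.append(f)
            thrs.append(t)
            gains.append(g)
        feats = np.concatenate(feats)
        thrs = np.concatenate(thrs)
        gains = np.concatenate(gains)
        total = gains.sum()
        if total <= 0:
            continue
        gains = gains / total * r2       # normalized mass, R^2-weighted
        for vi, v in enumerate(predictors):
            sel = feats == vi
            bp[v].extend(thrs[sel].tolist())
            ms[v].extend(gains[sel].tolist())

    breakpoints: dict[str, np.ndarray] = {}
    masses: dict[str, np.ndarray] = {}
    env_range: dict[str, tuple[float, float]] = {}
    for vi, v in enumerate(predictors):
        t = np.asarray(bp[v])
        m = np.asarray(ms[v])
        order = np.argsort(t, kind="stable")
        t, m = t[order], m[order]
        uniq, inv = np.unique(t, return_inverse=True)
        agg = np.zeros(uniq.size)
        np.add.at(agg, inv, m)
        breakpoints[v] = uniq
        masses[v] = agg
        env_range[v] = (float(X[:, vi].min()), float(X[:, vi].max()))
    return TurnoverModel(predictors, breakpoints, masses, env_range,
                         n_trees, n_used, seed)


# ---------------------------------------------------------------------------
# Transformation and offset

def transform_climate(model: TurnoverModel,
                      layers: dict[str, RasterGrid]) -> dict[str, RasterGrid]:
    """Map climate layers into genomic-composition space, per predictor."""
    missing = [v for v in model.predictors if v not in layers]
    if missing:
        raise ValueError(f"missing predictor layer(s): {missing}")
    check_conformable(*[layers[v] for v in model.predictors])
    return {v: layers[v].copy_with(
        model.cumulative_importance(v, layers[v].data))
        for v in model.predictors}


def genomic_offset(model: TurnoverModel, current: dict[str, RasterGrid],
                   future: dict[str, RasterGrid], scenario: str = "",
                   ssp: str = "", period: str = "", gcm: str = "") -> OffsetSurface:
    """Euclidean distance between future and current genomic compositions."""
    check_conformable(*[current[v] for v in model.predictors],
                      *[future[v] for v in model.predictors])
    cur = transform_climate(model, current)
    fut = transform_climate(model, future)
    sq = np.zeros(cur[model.predictors[0]].shape)
    for v in model.predictors:
        sq += (fut[v].data - cur[v].data) ** 2
    return OffsetSurface(cur[model.predictors[0]].copy_with(np.sqrt(sq)),
                         scenario, ssp, period, gcm)


def aggregate_scenarios(surfaces: list[OffsetSurface]) -> dict[tuple[str, str], OffsetSurface]:
    """Cellwise mean offset per (SSP, period) group across GCM replicates."""
    if not surfaces:
        raise ValueError("no offset surfaces to aggregate")
    groups: dict[tuple[str, str], list[OffsetSurface]] = {}
    for s in surfaces:
        groups.setdefault((s.ssp, s.period), []).append(s)
    out: dict[tuple[str, str], OffsetSurface] = {}
    for key, members in groups.items():
        check_conformable(*[m.grid for m in members])
        mean = np.mean([m.grid.data for m in members], axis=0)
        out[key] = OffsetSurface(members[0].grid.copy_with(mean),
                                 scenario=f"{key[0]}_{key[1]}_mean",
                                 ssp=key[0], period=key[1], gcm="ensemble")
    return out


def compare_landscapes(offset: OffsetSurface, regions: np.ndarray,
                       min_cells: int = 10) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pairwise rank-sum tests of offset between landscape regions.

    ``regions`` labels every cell (same shape as the offset grid; empty
    string or None = unassigned).  Regions with fewer than ``min_cells``
    cells are excluded with a warning.  All pairs are tested two-sided by
    Wilcoxon rank-sum and BH-adjusted; per-region medians are returned
    alongside.
    """
    regions = np.asarray(regions)
    if regions.shape != offset.grid.shape:
        raise ValueError("region labels not conformable with offset grid")
    vals = offset.grid.data
    labels = [r for r in pd.unique(regions.ravel()) if r not in ("", None)]
    groups: dict[str, np.ndarray] = {}
    for lab in labels:
        v = vals[regions == lab]
        v = v[~np.isnan(v)]
        if v.size < min_cells:
            logger.warning("compare_landscapes: region %r has %d < %d cells, excluded",
                           lab, v.size, min_cells)
            continue
        groups[str(lab)] = v
    if len(groups) < 2:
        raise ValueError("need >= 2 usable regions")
    medians = {lab: float(np.median(v)) for lab, v in groups.items()}
    names = sorted(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if np.array_equal(np.sort(a), np.sort(b)):
                pval = 1.0
            else:
                pval = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            rows.append({"region_a": names[i], "region_b": names[j], "p": pval})
    df = pd.DataFrame(rows)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df, medians


def rank_variables(model: TurnoverModel) -> list[str]:
    """Predictors ordered by overall importance (ties broken alphabetically)."""
    imp = model.importance
    return sorted(model.predictors, key=lambda v: (-imp[v], v))


def ranking_stability(models: list[TurnoverModel]) -> float:
    """Mean pairwise Spearman correlation of importance vectors across fits.

    Below ~0.5 the ranking should be treated as noise-driven.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models")
    preds = models[0].predictors
    vecs = [np.array([m.importance[v] for v in preds]) for m in models]
    rhos = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            rho = stats.spearmanr(vecs[i], vecs[j]).statistic
            rhos.append(0.0 if np.isnan(rho) else rho)
    return float(np.mean(rhos))
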
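"""Synthetic landscapes, demes, and genotypes with planted adaptive loci.

The generator stands in for the field data of a range-wide landscape
genomics study: spatially autocorrelated bioclim-style rasters for a
"current" and a shifted "future" scenario, elevation and slope, demes
scattered over the grid, and 0/1/2 genotype matrices in which neutral
loci follow Balding-Nichols island-model drift around an ancestral
frequency while adaptive loci track one environmental predictor through
a logistic cline in deme allele frequency:

    neutral:   p_deme ~ Beta(p(1-F)/F, (1-p)(1-F)/F),  p ~ U(0.1, 0.9)
    adaptive:  p_deme = logistic(logit(p) + slope * z(env_driver))

F is the target FST, so the multi-locus Weir-Cockerham estimate on
neutral loci converges to ``fst_target`` — the closed-form oracle the
test suite leans on.  A truth record of planted loci enables power and
false-discovery scoring of every downstream scan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .genio import GenotypeMatrix, MISSING
from .raster import RasterGrid

logger = logging.getLogger(__name__)

#: Realistic mean/SD used to put simulated predictors on bioclim-like scales
#: (annual precipitation in mm, seasonality in CV%, temperatures in deg C).
BIOCLIM_BASELINES: dict[str, tuple[float, float]] = {
    "bio12": (500.0, 150.0),   # annual precipitation
    "bio15": (60.0, 15.0),     # precipitation seasonality
    "bio2": (12.0, 2.0),       # mean diurnal range
    "bio8": (10.0, 3.0),       # mean temp of wettest quarter
    "bio9": (-2.0, 3.0),       # mean temp of driest quarter
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study system.

    Defaults describe the standard study conditions used throughout the
    test suite: 20 demes x 20 diploid individuals, 2000 neutral loci at
    FST 0.05, 50 adaptive loci with log-odds cline slope 2 per SD of the
    driver predictor, a 40 x 40 landscape with ~5-cell autocorrelation
    range, and the five weakly correlated bioclim predictors used in
    genotype-environment association work.
    """

    n_demes: int = 20
    n_per_deme: int = 20
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 50
    fst_target: float = 0.05
    cline_slope: float = 2.0
    grid_shape: tuple[int, int] = (40, 40)
    autocorr_range: float = 5.0
    env_names: tuple[str, ...] = ("bio12", "bio15", "bio2", "bio8", "bio9")
    driver: str | None = None            # defaults to env_names[0]
    future_shift: dict[str, float] = field(
        default_factory=lambda: {"bio12": -1.0, "bio15": 0.5, "bio2": 0.5,
                                 "bio8": 1.0, "bio9": 1.0})
    future_noise_sd: float = 0.05
    gradient_weight: float = 1.0         # strength of the west-east ramp
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("n_demes", self.n_demes), ("n_per_deme", self.n_per_deme),
                        ("n_neutral_loci", self.n_neutral_loci)):
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.n_adaptive_loci < 0:
            raise ValueError("n_adaptive_loci must be >= 0")
        if not (0.0 < self.fst_target < 1.0):
            raise ValueError(f"fst_target must be in (0,1), got {self.fst_target}")
        if min(self.grid_shape) < 2:
            raise ValueError(f"degenerate grid {self.grid_shape}: dims must be >= 2")
        if self.driver is None:
            self.driver = self.env_names[0]
        if self.driver not in self.env_names:
            raise ValueError(f"driver {self.driver!r} not among env_names")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent, reproducible stream per stage."""
        return np.random.default_rng([int(self.seed) % (2 ** 31), stream])


@dataclass
class TruthRecord:
    """Ground truth of planted adaptive loci for power/FDR scoring."""

    adaptive_locus_ids: list[str]
    driver_predictor: dict[str, str]
    cline_slope_used: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


# ---------------------------------------------------------------------------
# Landscape

def _autocorr_field(shape, autocorr_range, rng, gradient_weight=0.0):
    """Standardized random field: smoothed white noise + west-east ramp."""
    z = rng.standard_normal(shape)
    if autocorr_range > 0:
        z = gaussian_filter(z, sigma=autocorr_range, mode="reflect")
    z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    if gradient_weight != 0.0:
        ramp = np.tile(np.linspace(-1.0, 1.0, shape[1]), (shape[0], 1))
        z = z + gradient_weight * ramp
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
    return z


def simulate_landscape(config: SimulationConfig) -> dict:
    """Generate current/future climate rasters plus elevation and slope.

    Returns a dict with keys ``current`` and ``future`` (predictor-name ->
    RasterGrid, in real bioclim-like units), ``elevation`` and ``slope``.
    The future layer is current + per-predictor shift (in predictor SD
    units) + independent cell noise of SD ``future_noise_sd``.
    """
    shape = tuple(config.grid_shape)
    current: dict[str, RasterGrid] = {}
    future: dict[str, RasterGrid] = {}
    for k, name in enumerate(config.env_names):
        rng = config.rng(100 + k)
        mu, sd = BIOCLIM_BASELINES.get(name, (0.0, 1.0))
        z = _autocorr_field(shape, config.autocorr_range, rng,
                            gradient_weight=config.gradient_weight)
        cur = mu + sd * z
        shift = config.future_shift.get(name, 0.0) * sd
        noise = (config.future_noise_sd * sd
                 * rng.standard_normal(shape)) if config.future_noise_sd else 0.0
        current[name] = RasterGrid(cur)
        future[name] = RasterGrid(cur + shift + noise)
    rng = config.rng(99)
    elev = RasterGrid(4000.0 + 600.0 * _autocorr_field(
        shape, config.autocorr_range, rng, gradient_weight=0.5))
    return {"current": current, "future": future,
            "elevation": elev, "slope": slope_from_elevation(elev)}


def slope_from_elevation(elev: RasterGrid) -> RasterGrid:
    """Slope magnitude by central finite differences of elevation."""
    gy, gx = np.gradient(elev.data, elev.cellsize)
    return elev.copy_with(np.hypot(gx, gy))


def place_demes(config: SimulationConfig) -> np.ndarray:
    """Distinct random cells for the demes; shape (n_demes, 2) of (row, col)."""
    nrows, ncols = config.grid_shape
    n_cells = nrows * ncols
    if config.n_demes > n_cells:
        raise ValueError("more demes than grid cells")
    flat = config.rng(98).choice(n_cells, size=config.n_demes, replace=False)
    return np.column_stack(np.unravel_index(flat, (nrows, ncols)))


def env_at_sites(layers: dict[str, RasterGrid], cells: np.ndarray) -> pd.DataFrame:
    """Extract predictor values at (row, col) cells into an env table."""
    data = {name: grid.data[cells[:, 0], cells[:, 1]]
            for name, grid in layers.items()}
    df = pd.DataFrame(data)
    df.index = [f"deme{i}" for i in range(len(cells))]
    return df


# ---------------------------------------------------------------------------
# Genotypes

def simulate_genotypes(config: SimulationConfig,
                       site_env: pd.DataFrame) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw genotypes for all demes; plant adaptive clines along the driver.

    ``site_env`` must hold one row per deme with columns covering
    ``config.env_names``.  Neutral deme frequencies are Balding-Nichols
    with F = ``fst_target``; adaptive deme frequencies follow a logistic
    cline in the z-scored driver predictor.  Genotypes are Binomial(2, f).
    """
    missing_cols = [c for c in config.env_names if c not in site_env.columns]
    if missing_cols:
        raise ValueError(f"site_env missing predictors: {missing_cols}")
    if len(site_env) != config.n_demes:
        raise ValueError("site_env must have one row per deme")

    rng = config.rng(1)
    F = config.fst_target
    d, L_n, L_a = config.n_demes, config.n_neutral_loci, config.n_adaptive_loci
    m = L_n + L_a

    p_anc = rng.uniform(0.1, 0.9, size=m)
    # Balding-Nichols drift for every locus; adaptive loci overwritten below.
    alpha = p_anc * (1 - F) / F
    beta = (1 - p_anc) * (1 - F) / F
    deme_freq = rng.beta(alpha[None, :], beta[None, :], size=(d, m))

    env = site_env[config.driver].to_numpy(dtype=float)
    z = (env - env.mean()) / (env.std() if env.std() > 0 else 1.0)
    n_clipped = 0
    for j in range(L_n, m):
        f = expit(logit(p_anc[j]) + config.cline_slope * z)
        clipped = np.clip(f, 0.001, 0.999)
        n_clipped += int(np.sum(clipped != f))
        deme_freq[:, j] = clipped
    if n_clipped:
        logger.info("simulate_genotypes: clipped %d cline frequencies to [0.001, 0.999]",
                    n_clipped)

    n = d * config.n_per_deme
    G = np.empty((n, m), dtype=np.int8)
    demes: list[str] = []
    samples: list[str] = []
    for i in range(d):
        rows = slice(i * config.n_per_deme, (i + 1) * config.n_per_deme)
        G[rows] = rng.binomial(2, deme_freq[i], size=(config.n_per_deme, m))
        demes += [f"deme{i}"] * config.n_per_deme
        samples += [f"deme{i}_ind{k}" for k in range(config.n_per_deme)]

    if config.missing_rate > 0:
        mask = rng.random(G.shape) < config.missing_rate
        G[mask] = MISSING

    pos = np.arange(1, m + 1, dtype=np.int64)
    gm = GenotypeMatrix(G, samples, demes, ["sim1"] * m, pos)
    adaptive_ids = [f"sim1:{p}" for p in pos[L_n:]]
    truth = TruthRecord(
        adaptive_locus_ids=adaptive_ids,
        driver_predictor={lid: config.driver for lid in adaptive_ids},
        cline_slope_used={lid: float(config.cline_slope) for lid in adaptive_ids},
    )
    return gm, truth


# ---------------------------------------------------------------------------
# Occurrences

def true_suitability(layers: dict[str, RasterGrid], driver: str,
                     threshold: float | None = None,
                     steepness: float = 8.0) -> RasterGrid:
    """Known suitability surface: sharp sigmoid on one predictor, in [0, 1].

    ``s = logistic(steepness * (x - threshold) / sd(x))``; the default
    threshold is the 80th percentile of the driver, so roughly a fifth of
    the landscape is suitable — a contrast presence/background models can
    actually learn from thinned occurrence draws.
    """
    x = layers[driver].data
    if threshold is None:
        threshold = float(np.quantile(x, 0.8))
    sd = float(x.std()) or 1.0
    return layers[driver].copy_with(expit(steepness * (x - threshold) / sd))


def simulate_occurrences(suitability: RasterGrid, n_points: int,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample presence cells with probability proportional to suitability.

    Sampling is without replacement while positive-suitability cells
    remain; only if ``n_points`` exceeds their number are duplicates
    drawn.  Returns an ``(n_points, 2)`` array of (row, col).
    """
    s = np.nan_to_num(suitability.data, nan=0.0).ravel()
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero suitability surface: nothing to sample")
    if n_points == 0:
        return np.empty((0, 2), dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = s / total
    n_pos = int((s > 0).sum())
    take = min(n_points, n_pos)
    flat = rng.choice(s.size, size=take, replace=False, p=p)
    if n_points > n_pos:
        extra = rng.choice(s.size, size=n_points - n_pos, replace=True, p=p)
        flat = np.concatenate([flat, extra])
    return np.column_stack(np.unravel_index(flat, suitability.shape))
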
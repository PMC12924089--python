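# Methods

This note records the models behind each stage, the defaults and why, what
the synthetic generator does and does not emulate, and the numerical and
design choices that were genuinely open.

## Synthetic study system

The generator emulates the data shape of a range-wide landscape-genomics
study of a low-dispersal montane bird: demes scattered over a rugged
landscape with a strong west–east moisture gradient, whole-genome SNPs, and
bioclim-style climate layers for current and future scenarios.

**Environmental fields.** Each predictor is Gaussian-kernel-smoothed white
noise (smoothing sigma = `autocorr_range` cells, default 5 on a 40×40 grid)
plus a linear west–east ramp (`gradient_weight`, default 1), standardized
and mapped onto realistic bioclim scales (e.g., annual precipitation
500 ± 150 mm, precipitation seasonality 60 ± 15 CV%, temperatures in °C).
The exact geostatistical family is not the point; what matters downstream
is spatial autocorrelation plus a dominant gradient, which this produces.
Elevation is an independent smoothed field (4000 ± 600 m); slope is its
central-finite-difference gradient magnitude.  Future layers are current +
a per-predictor shift expressed in predictor SD units + independent cell
noise (SD 0.05 predictor-SD); GCM spread is emulated by three
noise-perturbed replicates of each shift, SSP/period severity by shift
multipliers (SSP5-8.5 ×1.6, 2081–2100 ×1.3).

**Genotypes.** Neutral loci follow the Balding–Nichols island model: an
ancestral frequency p ~ U(0.1, 0.9) per locus and deme frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) with F equal to the target F_ST — chosen
precisely because the multi-locus Weir–Cockerham estimate converges to F,
giving the test suite a closed-form oracle (checked to ±0.02 at 2000
loci).  Adaptive loci replace drift with a logistic cline
`f_deme = logistic(logit(p) + slope · z(driver))` in the z-scored driver
predictor across demes (default driver: annual precipitation, slope 2 per
SD, clipped to [0.001, 0.999]).  Genotypes are Binomial(2, f_deme).
Defaults: 20 demes × 10–20 individuals, 2000 neutral + 50 adaptive loci,
F_ST 0.05.

**What is *not* emulated** — and hence what passing tests cannot show:
linkage disequilibrium beyond deme sampling (LD pruning is exercised on
deliberately duplicated columns), hierarchical or admixed population
structure (demes are exchangeable given the island model), coalescent
history, genotyping error and missingness structure (a uniform
missing-rate knob only exercises the I/O paths), and any correlation
between adaptive loci.  Real data add all of these; the suite demonstrates
correctness of the machinery and calibration under the stated model, not
robustness to every field complication.

**Occurrences.** Presences are drawn without replacement with probability
proportional to a known suitability truth.  The truth is a sharp sigmoid
on the driver (threshold at its 80th percentile, steepness 8/SD): with
presence draws thinned by suitability, a *broad* suitability surface caps
the achievable AUC/TSS of any learner near chance, so a contrast sharp
enough to be learnable is part of the study conditions, not a tuning knob.

## Per-locus statistics

F_ST is the Weir & Cockerham (1984) two-level θ with variance components
a, b, c; multi-locus values are ratio-of-sums (Σa/Σ(a+b+c)), matching the
VCFtools convention; negative per-locus estimates are reported as-is.
Loci with fewer than two groups of ≥2 non-missing samples, or monomorphic
over the used samples, are skipped.  Heterozygosity is the per-sample
proportion of heterozygous calls among non-missing loci, averaged per
group.  LD pruning slides a window (default 50 loci, step 5) and greedily
drops the later locus of any pair with dosage r² > 0.2; the tie-break
(drop the larger position) makes it deterministic.

## Latent-factor association scan

The scan is the deterministic ridge/least-squares reading of the
latent-factor mixed model rather than a stochastic MCMC fit: identical
estimand, reproducible outputs.  Steps: center genotypes (mean-imputing
missing calls) and the predictor; estimate K latent factors as the top-K
left singular vectors of the genotype matrix with the predictor regressed
out; per-locus OLS on [predictor, factors]; calibrate z by the genomic
inflation factor λ = median(z²)/0.4549 (the χ²₁ median — drift under the
island model overdisperses z, and λ ≈ 3 is typical at the default
conditions, so calibration is essential); two-sided p from the calibrated
χ²; BH q-values, hits at q < 0.01.  K defaults to 4.  Constant loci get
p = 1 and a log flag.  A replicate-averaging hook (`n_runs`) averages z
over randomized-SVD factor estimates for API parity with
replicate-averaged stochastic fits; the default single run uses the exact
SVD.  With several predictors the factors are estimated once on the
jointly residualised matrix and shared across the univariate tests.

## Redundancy analysis

Centered genotypes are regressed on the standardized predictor matrix
(condition number checked; near-collinear input is refused); the fitted
values are SVD-decomposed into constrained axes; locus loadings are
correlations with axis scores; a locus is an outlier when its loading
z-score (per axis, over loci) exceeds 3.5 on any of the first three axes.
Genotypes enter at the individual level (the per-deme-frequency variant
was the other defensible choice; individual-level matches how the
ordination is usually run and keeps the locus universe identical to the
latent-factor scan, which the core-candidate intersection requires).
Axis variance fractions are constrained eigenvalues over total genotype
variance.

## Gradient-forest turnover and offset

Per locus, a `RandomForestRegressor` (default 500 trees, mtry = ⌈p/3⌉,
bootstrap + out-of-bag scoring) predicts per-deme allele frequency from
the predictors.  Every internal split contributes its impurity reduction
at its threshold; per locus these are normalized to unit mass and weighted
by the OOB R² truncated at zero (non-positive-R² loci drop out).  Summed
over loci and accumulated along each predictor these masses form the
cumulative-importance step function F_v: monotone, right-continuous,
F(min) = 0, F(max) = overall importance (the sum identity holds to 1e-9 by
construction).  No within-bin density standardization is applied — the
accumulation is deliberately the raw split-mass version: simpler, monotone
by construction, and the recovery properties (driver ranked first,
offset tracking displacement) hold without it.  Climate outside the fitted
range is clamped to the range endpoints, where the step functions are flat
anyway — the model cannot extrapolate turnover it never saw.  The site
order is canonicalized (sorted by site label) before fitting so the model
is invariant to row permutation of the input tables.

Offset is the Euclidean distance between composition vectors; it is a true
metric in composition space (symmetry and the triangle inequality are
property-tested).  One caution established during validation: the
cellwise correlation between offset and raw driver displacement is
intrinsically limited by where cells sit on the turnover curve — even the
*true* cline turnover function yields Spearman ρ ≈ 0.65–0.7 under a
displacement ramp aligned with the driver's own spatial gradient, because
the largest shifts then fall on range-edge cells where F is flat.  The
end-to-end check therefore draws the future driver layer as an independent
realization of the same field family (per-cell displacements of both signs
and wide dynamic range), under which the fitted model reaches mean
ρ ≈ 0.74 over five seeds.

## Distances and MRM

Geographic distance is great-circle (haversine, R = 6371 km) on deme
coordinates; environmental distance is Euclidean over z-scored selected
predictors (the standardization choice is ours — unstandardized distances
would let large-unit predictors dominate); genetic distance is pairwise
multi-locus Weir–Cockerham F_ST, used raw rather than linearized as
F_ST/(1−F_ST).  MRM regresses lower-triangle vectors with an intercept;
inference permutes rows/columns of the *response* matrix jointly (the
standard Mantel-style scheme) with the add-one rule
p = (1 + #{|stat*| ≥ |stat|})/(n_perm + 1), so p can never be 0 at finite
permutations.  Default 999 permutations.

## Suitability ensemble and resistance

VIF filtering iteratively removes the predictor with the largest
1/(1−R²) until all are ≤ 2.5, dropping the larger column index on ties.
The ensemble uses two members — logistic regression and a random forest —
because the evaluation/weighting logic, not algorithm breadth, is the
specified behavior: per member, three random 70/30 presence+background
splits; TSS maximized over a 101-point threshold grid; AUC by rank
statistic; members with mean TSS ≤ 0.60 get weight 0, the rest weight
∝ TSS; the ensemble surface is the weighted mean of member probability
surfaces over the grid.  1000 background points are drawn uniformly.

Resistance: for each terrain feature (elevation, moving-window elevation
SD, slope) the absolute deviation of every cell from the feature's mean
over occupied cells, min–max normalized to [0, 1] *before* averaging —
the one material interpretation choice here, made so no feature dominates
through its units — averaged with equal weights together with inverted,
normalized suitability, then linearly rescaled to [1, 10].  A constant
combined surface degenerates to all-1 with a warning.  The binarization
threshold for suitable-area fractions defaults to the TSS-maximizing
threshold.

## Orchestration, sizes and determinism

The pipeline config is a strict YAML schema (unknown keys rejected); every
stage draws from a stream derived from the single run seed, and all
outputs — VCF, CSV/TSV, ASCII rasters, JSON — are byte-identical across
reruns.  The default demo sizes (200 individuals × 2050 loci, 40×40 grid,
150 trees, gradient-forest ranking on a 200-locus subsample) were chosen
as the smallest system on which every stage's statistical behavior is
comfortably expressed; the calibration and power checks run 10 replicates
at 400 × 2000.

## Known limitations

* The island-model generator cannot produce confounding between structure
  and environment beyond what its exchangeable drift induces; the
  K = 0 inflation demonstration constructs confounding explicitly.
* Turnover functions are step functions supported on observed split
  thresholds; with few sites they are coarse, and offset contrasts between
  climatically similar cells are correspondingly quantized.
* The resistance surface is a hypothesis-encoding visualization aid, not a
  fitted movement model; no connectivity (circuit/least-cost) analysis is
  included.
* VCF support is the minimal GT-only biallelic dialect; likelihoods,
  phasing and imputation are out of scope.
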
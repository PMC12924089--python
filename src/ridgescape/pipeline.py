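"""Configuration-driven orchestration of the full synthetic-to-report workflow.

``run()`` executes the stages in dependency order — simulate ->
population structure -> genotype-environment association -> genomic
offset -> suitability & resistance — writing plain-text artifacts
(VCF, CSV/TSV, ASCII rasters, JSON) plus a deterministic summary report
into the output directory.  Every random stage draws from a stream
derived from the single run seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genio, gea, gforest, landscape as lsc, popstruct, simdata
from .raster import RasterGrid

logger = logging.getLogger(__name__)

#: multipliers applied to the configured future shift per scenario axis
SSP_SCALES = {"ssp245": 1.0, "ssp585": 1.6}
PERIOD_SCALES = {"2070": 1.0, "2090": 1.3}
N_GCM = 3


@dataclass
class RunConfig:
    """Validated knob set for one pipeline run (unknown keys rejected)."""

    seed: int = 0
    outdir: str = "results/run"
    # simulation
    n_demes: int = 20
    n_per_deme: int = 10
    n_neutral_loci: int = 2000
    n_adaptive_loci: int = 50
    fst_target: float = 0.05
    cline_slope: float = 2.0
    grid_shape: tuple[int, int] = (40, 40)
    autocorr_range: float = 5.0
    env_names: tuple[str, ...] = ("bio12", "bio15", "bio2", "bio8", "bio9")
    missing_rate: float = 0.0
    # population structure
    n_pca_axes: int = 10
    n_perm: int = 999
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2
    # association scan
    K: int = 4
    fdr: float = 0.01
    r_threshold: float = 0.6
    sd_limit: float = 3.5
    rda_axes: int = 3
    n_extreme: int = 5
    # turnover / offset
    n_trees: int = 150
    rank_max_loci: int = 200
    # suitability / resistance
    vif_threshold: float = 2.5
    tss_threshold: float = 0.60
    background_n: int = 1000
    n_occurrences: int = 230
    sdm_repeats: int = 3
    # stage toggles
    run_popstruct: bool = True
    run_gea: bool = True
    run_offset: bool = True
    run_landscape: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "env_names" in raw:
            raw["env_names"] = tuple(raw["env_names"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["env_names"] = list(self.env_names)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def sim_config(self) -> simdata.SimulationConfig:
        return simdata.SimulationConfig(
            n_demes=self.n_demes, n_per_deme=self.n_per_deme,
            n_neutral_loci=self.n_neutral_loci,
            n_adaptive_loci=self.n_adaptive_loci,
            fst_target=self.fst_target, cline_slope=self.cline_slope,
            grid_shape=self.grid_shape, autocorr_range=self.autocorr_range,
            env_names=self.env_names, missing_rate=self.missing_rate,
            seed=self.seed)


def quadrant_regions(shape: tuple[int, int]) -> np.ndarray:
    """Partition the grid into four landscape quadrants (NW/NE/SW/SE)."""
    nrows, ncols = shape
    out = np.empty(shape, dtype=object)
    out[: nrows // 2, : ncols // 2] = "NW"
    out[: nrows // 2, ncols // 2:] = "NE"
    out[nrows // 2:, : ncols // 2] = "SW"
    out[nrows // 2:, ncols // 2:] = "SE"
    return out


def cell_coords(cells: np.ndarray, shape: tuple[int, int]) -> pd.DataFrame:
    """Map grid cells onto a pseudo lat/lon frame (0.05 degree cells)."""
    lat = 28.0 + (shape[0] - 1 - cells[:, 0]) * 0.05
    lon = 80.0 + cells[:, 1] * 0.05
    return pd.DataFrame({"lat": lat, "lon": lon},
                        index=[f"deme{i}" for i in range(len(cells))])


def scenario_offsets(model: gforest.TurnoverModel, current, config: RunConfig,
                     sd_by_name: dict[str, float]):
    """Offset surfaces for every SSP x period x GCM replicate."""
    sim = config.sim_config()
    surfaces = []
    for si, (ssp, s_scale) in enumerate(sorted(SSP_SCALES.items())):
        for pi, (period, p_scale) in enumerate(sorted(PERIOD_SCALES.items())):
            for g in range(N_GCM):
                rng = np.random.default_rng(
                    [config.seed % (2 ** 31), 500, si * 10 + pi, g])
                future = {}
                for name in model.predictors:
                    sd = sd_by_name[name]
                    shift = sim.future_shift.get(name, 0.0) * sd * s_scale * p_scale
                    noise = 0.05 * sd * rng.standard_normal(current[name].shape)
                    future[name] = current[name].copy_with(
                        current[name].data + shift + noise)
                surfaces.append(gforest.genomic_offset(
                    model, current, future,
                    scenario=f"{ssp}_{period}_gcm{g}", ssp=ssp, period=period,
                    gcm=f"gcm{g}"))
    return surfaces


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run directory."""


from contextlib import contextmanager


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the summary report dict.

    Stages run in dependency order; a failure halts with the failing
    stage named, retaining any outputs already written.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"seed": config.seed}

    # ---- stage: simulate -------------------------------------------------
    with _stage("simulate"):
        sim = config.sim_config()
        land = simdata.simulate_landscape(sim)
        cells = simdata.place_demes(sim)
        site_env = simdata.env_at_sites(land["current"], cells)
        gm, truth = simdata.simulate_genotypes(sim, site_env)
        genio.write_vcf(gm, out / "genotypes.vcf")
        site_env.to_csv(out / "site_env.csv")
        truth.to_json(out / "truth.json")
        for name, grid in land["current"].items():
            grid.write_ascii(out / f"current_{name}.asc")
        land["elevation"].write_ascii(out / "elevation.asc")
        report["n_samples"] = gm.n_samples
        report["n_loci"] = gm.n_loci

        het = genio.heterozygosity(gm)
        report["heterozygosity_range"] = [round(min(het.values()), 4),
                                          round(max(het.values()), 4)]
        _, fst_all = genio.wc_fst(gm)
        report["multilocus_fst"] = round(fst_all, 4)

        env_per_sample = site_env.loc[gm.demes].reset_index(drop=True)

    # ---- stage: population structure ------------------------------------
    if config.run_popstruct:
        with _stage("popstruct"):
            kept = genio.ld_prune(gm, config.ld_window, config.ld_step, config.ld_r2_max)
            pruned = gm.subset_loci(kept)
            scores, var_frac = popstruct.pca_genotypes(pruned, config.n_pca_axes)
            pd.DataFrame(scores, index=gm.samples).to_csv(out / "pca_scores.csv")
            report["n_ld_pruned"] = int(len(kept))
            report["pca_var_frac"] = [round(float(v), 4) for v in var_frac[:4]]

            coords = cell_coords(cells, sim.grid_shape)
            dset = popstruct.distance_matrices(coords, site_env, gm, list(sim.env_names))
            mres = popstruct.mrm(dset.genetic,
                                 {"geographic": dset.geographic,
                                  "environmental": dset.environmental},
                                 n_perm=config.n_perm, seed=config.seed + 11)
            report["mrm"] = {
                "beta_geographic": round(float(mres.beta[0]), 6),
                "beta_environmental": round(float(mres.beta[1]), 6),
                "p_geographic": round(float(mres.p_perm[0]), 4),
                "p_environmental": round(float(mres.p_perm[1]), 4),
                "r2": round(mres.r2, 4), "p_r2": round(mres.p_r2, 4)}

    # ---- stage: association scan ----------------------------------------
    core_ids: set[str] = set()
    selected = list(sim.env_names)
    if config.run_gea:
        with _stage("gea"):
            freqs, _ = gm.deme_allele_freq()
            freq_df = pd.DataFrame(freqs, columns=gm.locus_ids, index=site_env.index)
            rank_model = gforest.fit_turnover(
                freq_df, site_env[list(sim.env_names)], n_trees=config.n_trees,
                seed=config.seed + 21, max_loci=config.rank_max_loci)
            importance = rank_model.importance
            sel = gea.select_predictors(site_env, importance, config.r_threshold)
            selected = sel.selected if len(sel.selected) >= 2 else list(sim.env_names)
            report["predictor_ranking"] = gforest.rank_variables(rank_model)
            report["selected_predictors"] = selected

            assoc = gea.lfmm_scan(gm, env_per_sample, selected, K=config.K,
                                  fdr=config.fdr)
            assoc.to_frame().to_csv(out / "lfmm.tsv", sep="\t", index=False)
            rda = gea.rda_outliers(gm, env_per_sample, selected,
                                   sd_limit=config.sd_limit, n_axes=config.rda_axes)
            cand = gea.core_candidates(assoc, rda)
            cand.to_frame().to_csv(out / "core_candidates.tsv", sep="\t", index=False)
            gea.write_candidates_bed(cand, out / "core_candidates.bed")
            core_ids = cand.core
            report["n_lfmm_hits"] = len(cand.lfmm_hits)
            report["n_rda_hits"] = len(cand.rda_hits)
            report["n_core"] = len(cand.core)
            report["rda_axis_var_frac"] = [round(float(v), 4)
                                           for v in rda.axis_var_frac[:3]]

            driver_env = env_per_sample[sim.driver].to_numpy()
            if cand.core:
                f_c, f_r, p_fst = gea.fst_contrast(
                    gm, driver_env, cand.core, n_extreme=config.n_extreme,
                    seed=config.seed + 31)
                report["fst_contrast"] = {
                    "median_candidate": round(float(np.median(f_c)), 4),
                    "median_random": round(float(np.median(f_r)), 4),
                    "p": float(f"{p_fst:.3g}")}

            truth_set = set(truth.adaptive_locus_ids)
            if truth_set:
                lf_rec = len(cand.lfmm_hits & truth_set) / len(truth_set)
                core_rec = len(cand.core & truth_set) / len(truth_set)
                core_fdr = (len(cand.core - truth_set) / len(cand.core)
                            if cand.core else 0.0)
                report["truth_recovery"] = {
                    "lfmm_recall": round(lf_rec, 4),
                    "core_recall": round(core_rec, 4),
                    "core_fdr": round(core_fdr, 4)}

    # ---- stage: genomic offset ------------------------------------------
    if config.run_offset:
        with _stage("offset"):
            freqs, _ = gm.deme_allele_freq()
            freq_df = pd.DataFrame(freqs, columns=gm.locus_ids, index=site_env.index)
            panel = sorted(core_ids) if len(core_ids) >= 10 else list(
                truth.adaptive_locus_ids) or gm.locus_ids[:50]
            model = gforest.fit_turnover(
                freq_df[panel], site_env[selected], n_trees=config.n_trees,
                seed=config.seed + 41)
            model.to_json(out / "turnover_model.json")
            sd_by_name = {n: simdata.BIOCLIM_BASELINES.get(n, (0.0, 1.0))[1]
                          for n in selected}
            current = {n: land["current"][n] for n in selected}
            surfaces = scenario_offsets(model, current, config, sd_by_name)
            agg = gforest.aggregate_scenarios(surfaces)
            regions = quadrant_regions(sim.grid_shape)
            offsets_summary = {}
            for (ssp, period), surf in sorted(agg.items()):
                surf.grid.write_ascii(out / f"offset_{ssp}_{period}.asc")
                pairs, medians = gforest.compare_landscapes(surf, regions)
                offsets_summary[f"{ssp}_{period}"] = {
                    "medians": {k: round(v, 5) for k, v in sorted(medians.items())},
                    "n_pairs_significant": int((pairs["q"] < 0.05).sum())}
            report["offset"] = offsets_summary
            report["offset_model_loci"] = model.n_loci_used

    # ---- stage: suitability and resistance ------------------------------
    if config.run_landscape:
        with _stage("landscape"):
            suit_truth = simdata.true_suitability(land["current"], sim.driver)
            occ = simdata.simulate_occurrences(
                suit_truth, config.n_occurrences,
                np.random.default_rng([config.seed % (2 ** 31), 61]))
            pd.DataFrame(occ, columns=["row", "col"]).to_csv(
                out / "occurrences.csv", index=False)

            rng = np.random.default_rng([config.seed % (2 ** 31), 62])
            shape = sim.grid_shape
            sample_flat = rng.choice(shape[0] * shape[1], size=500, replace=False)
            sample_cells = np.column_stack(np.unravel_index(sample_flat, shape))
            env_cells = pd.DataFrame(
                {n: land["current"][n].data[sample_cells[:, 0], sample_cells[:, 1]]
                 for n in sim.env_names})
            retained = lsc.vif_filter(env_cells, config.vif_threshold)
            report["vif_retained"] = retained

            ens = lsc.fit_ensemble({n: land["current"][n] for n in retained}, occ,
                                   background_n=config.background_n,
                                   n_repeats=config.sdm_repeats,
                                   tss_threshold=config.tss_threshold,
                                   seed=config.seed + 63)
            ens.suitability.write_ascii(out / "suitability.asc")
            with open(out / "ensemble_report.json", "w") as fh:
                json.dump(ens.report(), fh, sort_keys=True, indent=1)
            report["ensemble_tss"] = {k: round(v["tss"], 4)
                                      for k, v in sorted(ens.member_scores.items())}

            feats = {"elevation": land["elevation"],
                     "elevation_sd": lsc.elevation_sd(land["elevation"]),
                     "slope": land["slope"]}
            res = lsc.resistance_surface(feats, ens.suitability, occ)
            res.grid.write_ascii(out / "resistance.asc")
            report["resistance"] = {
                "min": round(float(np.nanmin(res.grid.data)), 6),
                "max": round(float(np.nanmax(res.grid.data)), 6)}
            regions = quadrant_regions(sim.grid_shape)
            frac = lsc.suitable_fraction(ens.suitability, ens.best_threshold, regions)
            report["suitable_fraction"] = {k: round(v, 4)
                                           for k, v in sorted(frac.items())}

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
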
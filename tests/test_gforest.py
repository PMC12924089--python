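"""Gradient-forest turnover engine, climate transform, genomic offset."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ridgescape.gforest import (OffsetSurface, TurnoverModel,
                                aggregate_scenarios, compare_landscapes,
                                fit_turnover, genomic_offset, rank_variables,
                                ranking_stability, transform_climate)
from ridgescape.raster import RasterGrid


def step_panel(n_sites=60, t_star=0.0, seed=0):
    """Single locus whose frequency is a step function of predictor A."""
    rng = np.random.default_rng(seed)
    env = pd.DataFrame({"A": rng.uniform(-2, 2, n_sites),
                        "B": rng.uniform(-2, 2, n_sites)})
    freqs = pd.DataFrame({"locus1": np.where(env["A"] > t_star, 0.8, 0.2)})
    return freqs, env


def toy_model():
    """Hand-built turnover model: importance 1.0 on A (mass at 0), none on B."""
    return TurnoverModel(
        predictors=["A", "B"],
        breakpoints={"A": np.array([0.0]), "B": np.array([], dtype=float)},
        masses={"A": np.array([1.0]), "B": np.array([], dtype=float)},
        env_range={"A": (-2.0, 2.0), "B": (-2.0, 2.0)},
        n_trees=1, n_loci_used=1, seed=0)


class TestFitTurnover:
    def test_step_function_truth_recovered(self):
        freqs, env = step_panel(t_star=0.3)
        model = fit_turnover(freqs, env, n_trees=200, mtry=2, seed=1)
        imp = model.importance
        assert imp["A"] > 10 * imp["B"]
        # >= 80% of A's cumulative mass within +-(range/10) of the step
        bp, ms = model.breakpoints["A"], model.masses["A"]
        window = (env["A"].max() - env["A"].min()) / 10
        near = np.abs(bp - 0.3) <= window
        assert ms[near].sum() >= 0.8 * ms.sum()

    def test_pure_noise_has_negligible_importance(self):
        freqs, env = step_panel(seed=2)
        step_total = sum(fit_turnover(freqs, env, n_trees=200,
                                      seed=1).importance.values())
        rng = np.random.default_rng(3)
        noise = pd.DataFrame({"locus1": rng.uniform(0.2, 0.8, len(env))})
        noise_total = sum(fit_turnover(noise, env, n_trees=200,
                                       seed=1).importance.values())
        assert noise_total < 0.05 * step_total

    def test_site_order_invariance(self):
        freqs, env = step_panel(seed=4)
        freqs.index = [f"s{i:02d}" for i in range(len(freqs))]
        env.index = freqs.index
        perm = np.random.default_rng(0).permutation(len(freqs))
        m1 = fit_turnover(freqs, env, n_trees=100, seed=9)
        m2 = fit_turnover(freqs.iloc[perm], env.iloc[perm], n_trees=100, seed=9)
        for v in m1.predictors:
            np.testing.assert_array_equal(m1.breakpoints[v], m2.breakpoints[v])
            np.testing.assert_array_equal(m1.masses[v], m2.masses[v])

    def test_cumulative_mass_sums_to_overall_importance(self):
        freqs, env = step_panel(seed=5)
        model = fit_turnover(freqs, env, n_trees=100, seed=2)
        for v in model.predictors:
            f_max = model.cumulative_importance(v, env[v].max())
            assert f_max == pytest.approx(model.importance[v], abs=1e-9)

    def test_all_constant_rejected(self):
        _, env = step_panel()
        const = pd.DataFrame({"locus1": np.full(len(env), 0.5)})
        with pytest.raises(ValueError, match="informative"):
            fit_turnover(const, env, n_trees=10)

    def test_json_round_trip(self, tmp_path):
        freqs, env = step_panel(seed=6)
        model = fit_turnover(freqs, env, n_trees=50, seed=3)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = TurnoverModel.from_json(path)
        for v in model.predictors:
            np.testing.assert_allclose(back.masses[v], model.masses[v])
            np.testing.assert_allclose(back.breakpoints[v], model.breakpoints[v])


class TestTransform:
    def test_minimum_climate_maps_to_zero_composition(self):
        model = toy_model()
        layers = {"A": RasterGrid(np.full((3, 3), -2.0)),
                  "B": RasterGrid(np.full((3, 3), -2.0))}
        comp = transform_climate(model, layers)
        assert np.all(comp["A"].data == 0.0)
        assert np.all(comp["B"].data == 0.0)

    def test_equal_climate_equal_composition(self):
        model = toy_model()
        layers = {"A": RasterGrid(np.array([[0.5, 0.5], [-1.0, 2.0]])),
                  "B": RasterGrid(np.zeros((2, 2)))}
        comp = transform_climate(model, layers)
        assert comp["A"].data[0, 0] == comp["A"].data[0, 1]

    def test_monotone_in_raw_predictor(self):
        freqs, env = step_panel(seed=7)
        model = fit_turnover(freqs, env, n_trees=100, seed=4)
        xs = np.linspace(-3, 3, 200)        # extends past the fitted range
        for v in model.predictors:
            fv = model.cumulative_importance(v, xs)
            assert np.all(np.diff(fv) >= 0)

    def test_missing_layer_named_in_error(self):
        model = toy_model()
        with pytest.raises(ValueError, match="B"):
            transform_climate(model, {"A": RasterGrid(np.zeros((2, 2)))})


class TestOffset:
    def layers(self, a, b):
        return {"A": RasterGrid(np.full((4, 4), float(a))),
                "B": RasterGrid(np.full((4, 4), float(b)))}

    def test_identity_scenario_zero_offset(self):
        model = toy_model()
        cur = self.layers(0.5, 0.0)
        off = genomic_offset(model, cur, cur)
        assert np.all(off.grid.data == 0.0)

    def test_shift_on_zero_importance_predictor_is_free(self):
        model = toy_model()
        off = genomic_offset(model, self.layers(0.5, 0.0), self.layers(0.5, 1.5))
        assert np.all(off.grid.data == 0.0)

    def test_offset_monotone_in_shift_magnitude(self):
        freqs, env = step_panel(seed=8)
        model = fit_turnover(freqs, env, n_trees=100, seed=5)
        cur = {"A": RasterGrid(np.full((4, 4), -1.5)),
               "B": RasterGrid(np.zeros((4, 4)))}
        means = []
        for shift in [0.0, 0.5, 1.0, 2.0, 3.0]:
            fut = {"A": cur["A"].copy_with(cur["A"].data + shift), "B": cur["B"]}
            means.append(genomic_offset(model, cur, fut).grid.data.mean())
        assert np.all(np.diff(means) >= 0)

    def test_offset_is_a_metric_on_compositions(self):
        freqs, env = step_panel(seed=9)
        model = fit_turnover(freqs, env, n_trees=100, seed=6)
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = rng.uniform(-2, 2, size=(3, 2))
            def comp(x):
                return np.array([model.cumulative_importance(v, x[i])
                                 for i, v in enumerate(model.predictors)])
            dab = np.linalg.norm(comp(a) - comp(b))
            dba = np.linalg.norm(comp(b) - comp(a))
            dac = np.linalg.norm(comp(a) - comp(c))
            dcb = np.linalg.norm(comp(c) - comp(b))
            assert dab == pytest.approx(dba)
            assert dab <= dac + dcb + 1e-12

    def test_grid_mismatch_rejected(self):
        model = toy_model()
        cur = self.layers(0.0, 0.0)
        fut = {"A": RasterGrid(np.zeros((5, 5))), "B": RasterGrid(np.zeros((5, 5)))}
        with pytest.raises(ValueError):
            genomic_offset(model, cur, fut)


class TestAggregate:
    def surf(self, value, ssp="ssp245", period="2070", gcm="g0"):
        return OffsetSurface(RasterGrid(np.full((3, 3), float(value))),
                             ssp=ssp, period=period, gcm=gcm)

    def test_identical_members_mean_is_member(self):
        agg = aggregate_scenarios([self.surf(2.0), self.surf(2.0, gcm="g1")])
        assert np.all(agg[("ssp245", "2070")].grid.data == 2.0)

    def test_constant_pair_averages(self):
        agg = aggregate_scenarios([self.surf(1.0), self.surf(3.0, gcm="g1")])
        assert np.all(agg[("ssp245", "2070")].grid.data == 2.0)

    def test_groups_kept_separate(self):
        agg = aggregate_scenarios([self.surf(1.0), self.surf(5.0, ssp="ssp585")])
        assert np.all(agg[("ssp245", "2070")].grid.data == 1.0)
        assert np.all(agg[("ssp585", "2070")].grid.data == 5.0)

    def test_mean_reduces_variance(self):
        rng = np.random.default_rng(1)
        members = [OffsetSurface(RasterGrid(rng.random((6, 6)) + 1.0),
                                 ssp="s", period="p", gcm=f"g{i}")
                   for i in range(3)]
        agg = aggregate_scenarios(members)[("s", "p")]
        assert agg.grid.data.var() <= min(m.grid.data.var() for m in members)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_scenarios([])


class TestCompareLandscapes:
    def regions(self, shape, labels):
        out = np.empty(shape, dtype=object)
        third = shape[1] // len(labels)
        for i, lab in enumerate(labels):
            out[:, i * third:(i + 1) * third] = lab
        return out

    def test_identical_regions_not_rejected(self):
        vals = np.tile(np.arange(10.0), (10, 2)).reshape(10, 20)
        surf = OffsetSurface(RasterGrid(vals))
        regions = self.regions((10, 20), ["a", "b"])
        df, med = compare_landscapes(surf, regions)
        assert df["p"].iloc[0] == 1.0
        assert med["a"] == med["b"]

    def test_shifted_region_strongly_rejected(self):
        rng = np.random.default_rng(0)
        vals = rng.random((10, 20))
        vals[:, 10:] += 1.0
        surf = OffsetSurface(RasterGrid(vals))
        df, _ = compare_landscapes(surf, self.regions((10, 20), ["a", "b"]))
        assert df["p"].iloc[0] < 1e-6

    def test_null_regions_rarely_rejected_after_bh(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            surf = OffsetSurface(RasterGrid(rng.standard_normal((10, 30))))
            df, _ = compare_landscapes(surf, self.regions((10, 30),
                                                          ["a", "b", "c"]))
            rejections += int((df["q"] < 0.05).any())
        assert rejections <= 5

    def test_small_region_excluded(self):
        regions = self.regions((10, 20), ["a", "b"])
        regions[0, 0] = "tiny"
        surf = OffsetSurface(RasterGrid(np.random.default_rng(1).random((10, 20))))
        df, med = compare_landscapes(surf, regions)
        assert "tiny" not in med


class TestRanking:
    def test_single_driver_ranks_first(self, planted_sim):
        sim = planted_sim
        cfg = sim["config"]
        freqs, _ = sim["gm"].deme_allele_freq()
        panel = pd.DataFrame(freqs, columns=sim["gm"].locus_ids,
                             index=sim["site_env"].index)
        adaptive = sorted(sim["truth"].adaptive_locus_ids,
                          key=lambda s: int(s.split(":")[1]))
        model = fit_turnover(panel[adaptive], sim["site_env"][list(cfg.env_names)],
                             n_trees=150, seed=0)
        assert rank_variables(model)[0] == cfg.driver

    def test_deterministic_given_seed(self):
        freqs, env = step_panel(seed=10)
        m1 = fit_turnover(freqs, env, n_trees=60, seed=7)
        m2 = fit_turnover(freqs, env, n_trees=60, seed=7)
        assert rank_variables(m1) == rank_variables(m2)
        for v in m1.predictors:
            np.testing.assert_array_equal(m1.masses[v], m2.masses[v])

    def test_noise_ranking_flagged_unstable(self):
        rng = np.random.default_rng(11)
        env = pd.DataFrame(rng.uniform(-2, 2, size=(40, 4)),
                           columns=list("ABCD"))
        models = []
        for seed in range(5):
            noise = pd.DataFrame(
                rng.uniform(0.2, 0.8, size=(40, 6)),
                columns=[f"l{i}" for i in range(6)])
            models.append(fit_turnover(noise, env, n_trees=60, seed=seed))
        assert ranking_stability(models) < 0.5
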
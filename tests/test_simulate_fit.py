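import numpy as np
import pytest

from socsim.registry import default_registry
from socsim.rothc import PoolState, SoilProfile, initialize_pools, run_years
from socsim.simulate import (
    FeasibilityError,
    _exp_model,
    _truncated_normal,
    draw_inputs,
    fit_ensemble,
    fit_exponential,
    simulate_uhtu_class,
    summarize_ensemble,
    time_to_fraction,
)

from _oracles import steady_state_active_pools
from conftest import make_uhtu


class TestDraws:
    def test_zero_sd_reproduces_means(self, registry):
        from dataclasses import replace

        u = make_uhtu(relative_sd=0.0, feasible=registry.keys())
        lu = registry["grassland"]
        lu0 = type(lu)(spec=replace(lu.spec, yield_sd=0.0), mgmt=lu.mgmt)
        d = draw_inputs(u, lu0, lu0.mgmt, 123)
        assert d["temps"] == pytest.approx(u.climate.temp_mean)
        assert d["precip"] == pytest.approx(u.climate.precip_mean)
        assert d["clay"] == pytest.approx(25.0)
        assert d["soc0"] == pytest.approx(60.0)
        assert d["yield_dm"] == pytest.approx(3.0)

    def test_same_seed_same_draw(self, registry):
        u = make_uhtu(feasible=registry.keys())
        lu = registry["maize__irr__left"]
        d1 = draw_inputs(u, lu, lu.mgmt, 5)
        d2 = draw_inputs(u, lu, lu.mgmt, 5)
        for key in d1:
            assert np.all(np.asarray(d1[key]) == np.asarray(d2[key]))

    def test_truncated_normal_respects_bounds_and_mean(self):
        rng = np.random.default_rng(0)
        draws = _truncated_normal(rng, 20.0, 2.0, lo=0.0, hi=100.0,
                                  size=10_000)
        assert np.all((draws >= 0.0) & (draws <= 100.0))
        # CLT: sample mean within 3 * sd / sqrt(n) of the mean
        assert abs(draws.mean() - 20.0) < 3.0 * 2.0 / 100.0


class TestFitExponential:
    def test_constant_series_returns_level_as_asymptote(self):
        fit = fit_exponential(np.full(40, 55.0))
        assert fit.attainable_soc == pytest.approx(55.0)
        assert fit.converged

    def test_noiseless_self_consistency(self):
        t = np.arange(87.0)
        series = _exp_model(t, 1.2, 0.03, 30.0)
        fit = fit_exponential(series)
        assert fit.K == pytest.approx(1.2, rel=1e-6)
        assert fit.alpha == pytest.approx(0.03, rel=1e-6)
        assert fit.attainable_soc == pytest.approx(40.0, rel=1e-6)

    def test_noisy_recovery_within_5pct(self):
        rng = np.random.default_rng(1)
        t = np.arange(87.0)
        clean = _exp_model(t, 1.2, 0.03, 30.0)
        errs = []
        for _ in range(100):
            fit = fit_exponential(clean + rng.normal(0.0, 0.5, t.size))
            errs.append(abs(fit.attainable_soc - 40.0) / 40.0)
        assert max(errs) < 0.05

    def test_start_year_reindexes_series(self):
        t = np.arange(107.0)
        series = np.concatenate([np.full(20, -1.0),
                                 _exp_model(np.arange(87.0), 0.9, 0.05, 20.0)])
        fit = fit_exponential(series, start_year=20)
        assert fit.alpha == pytest.approx(0.05, rel=1e-6)
        assert fit.soc0_used == pytest.approx(20.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([1.0, 2.0]))

    def test_asymptote_insensitive_to_initial_state_near_equilibrium(self):
        # Two kernel runs whose pools start 5 % below / above the steady
        # state fit to the same attainable SOC within 1 %.
        a = np.full(12, 1.0)
        cover = np.ones(12)
        water, pan = np.full(12, 100.0), np.full(12, 60.0)
        plant, clay = np.full(12, 0.25), 25.0
        x = steady_state_active_pools(plant, np.zeros(12), a, np.ones(12),
                                      0.6 * np.ones(12), 1.44, clay)
        atts = []
        for factor in (0.95, 1.05):
            state = PoolState(*(factor * x), 8.0)
            series, _ = run_years(state, a, cover, water, pan, plant,
                                  np.zeros(12), 1.44, clay, years=250)
            atts.append(fit_exponential(series).attainable_soc)
        assert atts[0] == pytest.approx(atts[1], rel=0.01)


class TestSummarize:
    def test_sd_matches_direct_formula_on_five_fits(self):
        from socsim.simulate import FitResult

        vals = [40.0, 42.0, 38.0, 45.0, 41.0]
        fits = [FitResult(K=v * 0.05, alpha=0.05, soc0_used=30.0, rss=0.0)
                for v in vals]
        s = summarize_ensemble(fits)
        assert s.attainable_mean == pytest.approx(np.mean(vals))
        assert s.attainable_sd == pytest.approx(np.std(vals, ddof=1))
        assert s.attainable_ci[0] < s.attainable_mean < s.attainable_ci[1]

    def test_identical_fits_zero_sd(self):
        from socsim.simulate import FitResult

        fits = [FitResult(K=2.0, alpha=0.05, soc0_used=30.0, rss=0.0)] * 5
        s = summarize_ensemble(fits)
        assert s.attainable_sd == 0.0

    def test_all_flagged_is_an_error(self):
        from socsim.simulate import FitError, FitResult

        bad = [FitResult(K=np.nan, alpha=np.nan, soc0_used=0.0, rss=np.nan,
                         converged=False)] * 3
        with pytest.raises(FitError):
            summarize_ensemble(bad)


class TestSimulateUhtuClass:
    def test_deterministic_given_master_seed(self, registry):
        u = make_uhtu(feasible=registry.keys())
        lu = registry["grassland"]
        e1 = simulate_uhtu_class(u, lu, n_iter=5, years=10, seed=7)
        e2 = simulate_uhtu_class(u, lu, n_iter=5, years=10, seed=7)
        assert np.array_equal(e1.trajectories, e2.trajectories)

    def test_zero_sds_collapse_to_single_trajectory(self, registry):
        u = make_uhtu(relative_sd=0.0, feasible=registry.keys())
        from dataclasses import replace

        lu = registry["wheat__irr__left"]
        lu0 = type(lu)(spec=replace(lu.spec, yield_sd=0.0), mgmt=lu.mgmt)
        ens = simulate_uhtu_class(u, lu0, n_iter=20, years=15, seed=3)
        spread = np.ptp(ens.trajectories, axis=0)
        assert np.all(spread == 0.0)

    def test_residues_left_dominates_removed(self, registry):
        u = make_uhtu(feasible=registry.keys())
        left = simulate_uhtu_class(u, registry["maize__irr__left"],
                                   n_iter=30, years=40, seed=11)
        removed = simulate_uhtu_class(u, registry["maize__irr__removed"],
                                      n_iter=30, years=40, seed=11)
        ml, mr = left.trajectories.mean(axis=0), removed.trajectories.mean(axis=0)
        assert np.all(ml[1:] >= mr[1:])

    def test_infeasible_class_raises(self, registry):
        u = make_uhtu(feasible=["grassland"])
        with pytest.raises(FeasibilityError):
            simulate_uhtu_class(u, registry["maize__irr__left"], n_iter=2,
                                years=5, seed=1)

    def test_ensemble_mean_stable_across_master_seeds(self, registry):
        u = make_uhtu(feasible=registry.keys())
        lu = registry["grassland"]
        finals = []
        sds = []
        for seed in (101, 202):
            ens = simulate_uhtu_class(u, lu, n_iter=100, years=30, seed=seed)
            finals.append(ens.trajectories[:, -1].mean())
            sds.append(ens.trajectories[:, -1].std(ddof=1))
        tol = 2.0 * max(sds) / np.sqrt(100)
        assert abs(finals[0] - finals[1]) < 2.0 * tol

    def test_forest_uses_litter_ramp(self, registry):
        u = make_uhtu(feasible=registry.keys())
        fid = "forest__broadleaf_deciduous__moist_warm_temperate"
        ens = simulate_uhtu_class(u, registry[fid], n_iter=5, years=30, seed=2)
        assert ens.trajectories.shape == (5, 31)

    def test_fitted_parameters_collapse_under_degenerate_uncertainty(
            self, registry):
        # With every input sd at zero the whole chain - trajectories and
        # fitted (K, alpha, attainable) - is identical across iterations.
        from dataclasses import replace

        u = make_uhtu(relative_sd=0.0, feasible=registry.keys())
        lu = registry["wheat__irr__left"]
        lu0 = type(lu)(spec=replace(lu.spec, yield_sd=0.0), mgmt=lu.mgmt)
        ens = simulate_uhtu_class(u, lu0, n_iter=5, years=86, seed=5)
        fits = fit_ensemble(ens)
        s = summarize_ensemble(fits)
        assert s.attainable_sd == pytest.approx(0.0, abs=1e-9)
        assert s.alpha_sd == pytest.approx(0.0, abs=1e-12)


def test_time_to_fraction_basic():
    series = 50.0 - 40.0 * np.exp(-0.1 * np.arange(87))
    t95 = time_to_fraction(series, 50.0)
    assert t95 == pytest.approx(np.log(20) / 0.1, abs=1.0)
    assert time_to_fraction(np.full(10, 5.0), 5.0) == 0
    slow = 50.0 - 40.0 * np.exp(-0.001 * np.arange(87))
    assert time_to_fraction(slow, 50.0) == 87
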
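"""Scenario engine: grids, objectives, selection and performance indicators."""

import numpy as np
import pandas as pd
import pytest

from conftest import flat_forcing, inert_baseline
from fishens.dynamics import SimulationResult, simulate
from fishens.economics import EconomicParams
from fishens.errors import ConfigurationError, DataError
from fishens.forcing import STOCKS, gen_baseline, make_forcing
from fishens.scenarios import (
    DEFAULT_BLIM,
    SCENARIOS,
    ScenarioDefinition,
    build_f_grid,
    clip_regimes,
    cumulative_yield,
    evaluate_grid,
    evaluate_objective,
    grid_matrix,
    objective_values,
    performance_indicators,
    profit_frame,
    select_optimal,
)
from fishens.structures import default_ensemble, single_stock_logistic


class TestGrid:
    def test_default_grid_size(self):
        regimes = build_f_grid(resolution=0.2)
        assert len(regimes) == 8**3  # 0, 0.2, ..., 1.4 per stock

    def test_single_value_ranges_give_one_regime(self):
        regimes = build_f_grid({s: (0.3, 0.3) for s in STOCKS}, resolution=0.1)
        assert len(regimes) == 1
        assert regimes[0].f == {s: 0.3 for s in STOCKS}

    def test_grid_contains_the_unfished_regime(self):
        regimes = build_f_grid(resolution=0.35)
        assert any(all(r.f[s] == 0.0 for s in STOCKS) for r in regimes)

    def test_bad_resolution_rejected(self):
        with pytest.raises(ConfigurationError):
            build_f_grid(resolution=0.0)

    def test_clipping_respects_harvest_rate_domain(self, ensemble):
        regimes = build_f_grid(resolution=0.2)
        clipped = clip_regimes(regimes, ensemble["ewe_like"])
        assert max(r.f[s] for r in clipped for s in STOCKS) <= 1.0
        full = clip_regimes(regimes, ensemble["mspm_like"])
        assert len(full) == len(regimes)


def _toy_result(years, catch_per_year, stock="cod"):
    T = len(years)
    zeros = {s: np.zeros(T) for s in STOCKS}
    catch = {s: np.zeros(T) for s in STOCKS}
    catch[stock] = np.asarray(catch_per_year, dtype=float)
    ones = {s: np.ones(T) for s in STOCKS}
    return SimulationResult(
        years=np.asarray(years), f={s: 0.0 for s in STOCKS},
        ssb=ones, juvenile=zeros, catch=catch, m2={}, seal_rate=zeros,
        collapsed={s: np.zeros(T, dtype=bool) for s in STOCKS},
    )


class TestCumulativeYield:
    def test_constant_catch_over_projection(self):
        years = np.arange(2014, 2033)
        result = _toy_result(years, np.full(19, 2.0))
        assert cumulative_yield(result, "cod") == pytest.approx(38.0)

    def test_hand_summed_three_year_trajectory(self):
        result = _toy_result([2014, 2015, 2016], [1.25, 0.5, 3.0])
        assert cumulative_yield(result, "cod") == pytest.approx(4.75)

    def test_missing_years_rejected(self):
        result = _toy_result([2014, 2015], [1.0, 1.0])
        with pytest.raises(DataError):
            cumulative_yield(result, "cod", years=np.arange(2014, 2033))


@pytest.fixture(scope="module")
def grid_eval(ensemble):
    forcing = make_forcing("BAU", "LSE", seed=1)
    baseline = gen_baseline(1)
    structure = ensemble["mspm_like"]
    regimes = clip_regimes(build_f_grid(resolution=0.35), structure)
    return evaluate_grid(structure, regimes, forcing, baseline)


class TestObjectives:
    def test_portfolio_objective_is_sum_of_fleet_objectives(self, grid_eval):
        pe = objective_values(grid_eval, SCENARIOS["PE"])
        fe = objective_values(grid_eval, SCENARIOS["FE"])
        pf = objective_values(grid_eval, SCENARIOS["PF"])
        np.testing.assert_allclose(pf, pe + fe, rtol=1e-10)

    def test_recovery_ratio_arithmetic(self):
        years = np.arange(2014, 2033)
        T = len(years)
        ssb = {"cod": np.full(T, 10.0), "herring": np.full(T, 3.0), "sprat": np.full(T, 2.0)}
        result = SimulationResult(
            years=years, f={s: 0.0 for s in STOCKS}, ssb=ssb,
            juvenile={s: np.zeros(T) for s in STOCKS},
            catch={s: np.zeros(T) for s in STOCKS}, m2={},
            seal_rate={s: np.zeros(T) for s in STOCKS},
            collapsed={s: np.zeros(T, dtype=bool) for s in STOCKS},
        )
        profits = pd.DataFrame(
            {k: np.zeros(T) for k in ("profit_bt", "profit_gn", "profit_pt", "profit_total")},
            index=pd.Index(years, name="year"),
        )
        pr = ScenarioDefinition("PR", "", blim={"herring": 1.0, "sprat": 1.0})
        assert evaluate_objective(result, profits, pr) == pytest.approx(2.0)

    def test_recovery_infeasible_below_blim(self):
        years = np.arange(2014, 2033)
        T = len(years)
        ssb = {"cod": np.full(T, 10.0), "herring": np.full(T, 3.0), "sprat": np.full(T, 2.0)}
        result = SimulationResult(
            years=years, f={s: 0.0 for s in STOCKS}, ssb=ssb,
            juvenile={s: np.zeros(T) for s in STOCKS},
            catch={s: np.zeros(T) for s in STOCKS}, m2={},
            seal_rate={s: np.zeros(T) for s in STOCKS},
            collapsed={s: np.zeros(T, dtype=bool) for s in STOCKS},
        )
        profits = pd.DataFrame(
            {k: np.zeros(T) for k in ("profit_bt", "profit_gn", "profit_pt", "profit_total")},
            index=pd.Index(years, name="year"),
        )
        pr = ScenarioDefinition("PR", "", blim={"herring": 5.0, "sprat": 1.0})
        assert evaluate_objective(result, profits, pr) is None


class TestSelection:
    def test_grid_argmax_matches_brute_force_rescan(self, grid_eval):
        """Dual route: vectorised selection vs. per-regime re-evaluation."""
        for name in ("PE", "FE", "PF"):
            scenario = SCENARIOS[name]
            sel = select_optimal(grid_eval, scenario)
            best_val, best_idx = -np.inf, None
            for i in range(grid_eval.sim.n_regimes):
                run = grid_eval.sim.extract(i)
                profits = grid_eval.extract_profit_frame(i)
                val = evaluate_objective(run, profits, scenario,
                                         grid_eval.econ.discount_rate)
                if val is not None and val > best_val:
                    best_val, best_idx = val, i
            assert sel.index == best_idx
            assert sel.objective == pytest.approx(best_val, rel=1e-9)

    def test_status_quo_returns_reference_exactly(self, grid_eval):
        sel = select_optimal(grid_eval, SCENARIOS["SQ"])
        assert sel.f == grid_eval.baseline.reference_F

    def test_portfolio_dominates_single_fleet_optima(self, grid_eval):
        pf_vals = objective_values(grid_eval, SCENARIOS["PF"])
        pf = select_optimal(grid_eval, SCENARIOS["PF"])
        for other in ("PE", "FE"):
            sel = select_optimal(grid_eval, SCENARIOS[other])
            assert pf.objective >= pf_vals[sel.index] - 1e-9

    def test_recovery_selection_respects_blim_post_hoc(self, grid_eval):
        sel = select_optimal(grid_eval, SCENARIOS["PR"])
        assert sel.feasible
        run = grid_eval.sim.extract(sel.index)
        window = (run.years >= 2028) & (run.years <= 2032)
        assert run.ssb["herring"][window].mean() > DEFAULT_BLIM["herring"]
        assert run.ssb["sprat"][window].mean() > DEFAULT_BLIM["sprat"]

    def test_infeasible_recovery_reported_explicitly(self, grid_eval):
        impossible = ScenarioDefinition("PR", "", blim={"herring": 1e9, "sprat": 1e9})
        sel = select_optimal(grid_eval, impossible)
        assert not sel.feasible
        assert all(sel.f[s] is None for s in STOCKS)

    def test_insensitivity_count_monotone_in_tolerance(self, ensemble):
        forcing = make_forcing("BAU", "LSE", seed=1)
        baseline = gen_baseline(1)
        structure = ensemble["gadget_like"]
        regimes = clip_regimes(build_f_grid(resolution=0.25), structure)
        ge = evaluate_grid(structure, regimes, forcing, baseline)
        counts = []
        for tol in (1e-12, 1e-6, 1e-2, 1e2):
            sel = select_optimal(ge, SCENARIOS["PE"], insensitivity_tol=tol)
            counts.append(len(sel.no_information))
        assert counts == sorted(counts)

    def test_schaefer_msy_selected_from_grid(self, yield_economics):
        """With profit == yield, the optimal harvest rate is r/2."""
        r, K = 0.5, 100.0
        structure = single_stock_logistic(r, K)
        forcing = flat_forcing(150)
        baseline = inert_baseline(K / 2)
        regimes = build_f_grid(
            {"cod": (0.0, 0.45), "herring": (0, 0), "sprat": (0, 0)}, resolution=0.05
        )
        ge = evaluate_grid(structure, regimes, forcing, baseline, yield_economics)
        sel = select_optimal(ge, SCENARIOS["PE"])
        assert sel.f["cod"] == pytest.approx(r / 2, abs=1e-9)


class TestIndicators:
    def _run(self, ensemble):
        forcing = make_forcing("BAU", "LSE", seed=1)
        baseline = gen_baseline(1)
        result = simulate(ensemble["mspm_like"], baseline.reference_F, forcing, baseline)
        profits = profit_frame(result, forcing.seal_biomass)
        return result, profits, baseline

    def test_thirteen_yearly_values_per_indicator(self, ensemble):
        result, profits, baseline = self._run(ensemble)
        series = performance_indicators(result, profits, baseline.reference_indicator_means)
        assert len(series.frame) == 13
        assert list(series.frame.index) == list(range(2020, 2033))

    def test_relative_change_arithmetic(self, ensemble):
        result, profits, baseline = self._run(ensemble)
        refs = dict(baseline.reference_indicator_means)
        series = performance_indicators(result, profits, refs)
        year = 2025
        ref = refs["ssb_cod"]
        expected = (result.ssb["cod"][result.years == year][0] - ref) / abs(ref)
        assert series.frame.loc[year, "ssb_cod"] == pytest.approx(expected, rel=1e-12)
        # X == ref -> 0 and X == 1.2 ref -> +0.2 by the same formula
        assert (ref - ref) / abs(ref) == 0.0
        assert (1.2 * ref - ref) / abs(ref) == pytest.approx(0.2)

    def test_zero_reference_flagged_no_information(self, ensemble):
        result, profits, baseline = self._run(ensemble)
        refs = dict(baseline.reference_indicator_means)
        refs["profit_bt"] = 0.0
        series = performance_indicators(result, profits, refs)
        assert "profit_bt" in series.no_information
        assert series.values_for("profit_bt") == [None] * 13
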
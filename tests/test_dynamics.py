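"""Population-dynamics core: recruitment, predation, seals and the annual step."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fishens.dynamics import (
    ForcingYear,
    StockState,
    predation_mortality,
    recruitment_beverton_holt,
    recruitment_hockey_stick,
    recruitment_ricker,
    seal_mortality,
    simulate,
    simulate_grid,
    step,
)
from fishens.errors import DomainError, ForcingError, RegimeError
from fishens.forcing import STOCKS, gen_baseline, make_forcing
from fishens.structures import (
    Predation,
    SealPredation,
    default_ensemble,
    single_stock_logistic,
)

UNIT_FORCING = ForcingYear(
    year=2014,
    growth_mult={s: 1.0 for s in STOCKS},
    recruit_mult={s: 1.0 for s in STOCKS},
    seal_biomass=1.0,
)


class TestRecruitment:
    def test_ricker_values(self):
        assert recruitment_ricker(0.0, a=2.0, b=1.0) == 0.0
        assert recruitment_ricker(1.0, a=2.0, b=1.0) == pytest.approx(2 * math.e**-1, rel=1e-12)
        # maximum at S = 1/b with value a/(b*e)
        b = 0.4
        peak = recruitment_ricker(1 / b, a=3.0, b=b)
        assert peak == pytest.approx(3.0 / (b * math.e), rel=1e-12)
        grid = np.linspace(0, 10, 2001)
        assert recruitment_ricker(grid, a=3.0, b=b).max() <= peak + 1e-12

    def test_beverton_holt_values(self):
        assert recruitment_beverton_holt(0.0, a=5.0, b=2.0) == 0.0
        assert recruitment_beverton_holt(2.0, a=5.0, b=2.0) == pytest.approx(2.5)
        assert recruitment_beverton_holt(1e12, a=5.0, b=2.0) == pytest.approx(5.0, rel=1e-9)

    def test_hockey_stick_values(self):
        assert recruitment_hockey_stick(0.0, a=4.0, s_break=2.0) == 0.0
        assert recruitment_hockey_stick(2.0, a=4.0, s_break=2.0) == 4.0
        assert recruitment_hockey_stick(5.0, a=4.0, s_break=2.0) == 4.0
        assert recruitment_hockey_stick(1.0, a=4.0, s_break=2.0) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "fn,kwargs",
        [
            (recruitment_ricker, dict(a=1.0, b=1.0)),
            (recruitment_beverton_holt, dict(a=1.0, b=1.0)),
            (recruitment_hockey_stick, dict(a=1.0, s_break=1.0)),
        ],
    )
    def test_negative_ssb_rejected(self, fn, kwargs):
        with pytest.raises(DomainError):
            fn(-0.1, **kwargs)


LINEAR_PRED = Predation(
    form="linear_pred_declining_prey",
    prey=("herring", "sprat", "juv_cod"),
    attack={"herring": 1.0, "sprat": 2.0, "juv_cod": 3.0},
    pool_half_sat=0.0,
    guard_max=2.0,
)
SAT_PRED = Predation(
    form="saturating_pred",
    prey=("herring", "sprat"),
    max_rate={"herring": 0.2, "sprat": 0.4},
    pred_half_sat=1.0,
    avail_half_sat={"herring": 3.0, "sprat": 3.0},
)


class TestPredation:
    def test_no_predator_no_mortality(self):
        prey = {"herring": 2.0, "sprat": 1.0, "juv_cod": 0.5}
        for form, params in [
            ("linear_pred_declining_prey", LINEAR_PRED),
            ("saturating_pred", SAT_PRED),
        ]:
            assert predation_mortality(0.0, "herring", prey, form, params) == 0.0

    def test_linear_form_direct_ratio(self):
        prey = {"herring": 2.0, "sprat": 0.0, "juv_cod": 0.0}
        m2 = predation_mortality(1.0, "herring", prey, "linear_pred_declining_prey", LINEAR_PRED)
        assert m2 == pytest.approx(0.5)

    def test_linear_form_declines_with_total_prey(self):
        lo = {"herring": 1.0, "sprat": 0.0, "juv_cod": 0.0}
        hi = {"herring": 2.0, "sprat": 0.0, "juv_cod": 0.0}
        m_lo = predation_mortality(1.0, "herring", lo, "linear_pred_declining_prey", LINEAR_PRED)
        m_hi = predation_mortality(1.0, "herring", hi, "linear_pred_declining_prey", LINEAR_PRED)
        assert m_lo > m_hi

    def test_linear_form_is_linear_in_predator(self):
        prey = {"herring": 3.0, "sprat": 2.0, "juv_cod": 0.4}
        m1 = predation_mortality(0.7, "sprat", prey, "linear_pred_declining_prey", LINEAR_PRED)
        m2 = predation_mortality(1.4, "sprat", prey, "linear_pred_declining_prey", LINEAR_PRED)
        assert m2 == 2.0 * m1

    def test_linear_division_guard_returns_configured_max(self):
        prey = {"herring": 0.0, "sprat": 0.0, "juv_cod": 0.0}
        m2 = predation_mortality(1.0, "herring", prey, "linear_pred_declining_prey", LINEAR_PRED)
        assert m2 == LINEAR_PRED.guard_max

    @given(
        pred=st.floats(0, 1e6),
        prey_h=st.floats(0, 1e6),
        prey_s=st.floats(0, 1e6),
        m_max=st.floats(0.01, 5.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_saturating_form_never_exceeds_cap(self, pred, prey_h, prey_s, m_max):
        params = Predation(
            form="saturating_pred",
            prey=("herring", "sprat"),
            max_rate={"herring": m_max, "sprat": m_max},
            pred_half_sat=0.5,
            avail_half_sat={"herring": 1.0, "sprat": 1.0},
        )
        prey = {"herring": prey_h, "sprat": prey_s}
        m2 = predation_mortality(pred, "herring", prey, "saturating_pred", params)
        assert 0.0 <= m2 <= m_max + 1e-12

    def test_negative_biomass_rejected(self):
        with pytest.raises(DomainError):
            predation_mortality(-1.0, "herring", {"herring": 1.0, "sprat": 0, "juv_cod": 0},
                                "linear_pred_declining_prey", LINEAR_PRED)


class TestSealMortality:
    LINEAR = SealPredation(form="linear", coeff={"cod": 0.05}, prey_half_sat={"cod": 1.0})
    SAT = SealPredation(
        form="saturating", coeff={"cod": 0.06}, seal_half_sat=0.5, prey_half_sat={"cod": 1.0}
    )

    def test_none_form_is_zero(self):
        assert seal_mortality(10.0, 5.0, "none", SealPredation(form="none")) == 0.0

    def test_linear_doubles_with_seal_biomass(self):
        r1 = seal_mortality(1.0, 2.0, "linear", self.LINEAR)
        r2 = seal_mortality(2.0, 2.0, "linear", self.LINEAR)
        assert r2 == pytest.approx(2 * r1)
        assert r1 > 0

    def test_linear_increases_with_prey(self):
        r_lo = seal_mortality(1.0, 1.0, "linear", self.LINEAR)
        r_hi = seal_mortality(1.0, 5.0, "linear", self.LINEAR)
        assert r_hi > r_lo

    def test_saturating_bounded_at_huge_seal_population(self):
        r = seal_mortality(1e9, 1e9, "saturating", self.SAT)
        assert r <= self.SAT.coeff["cod"] + 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            seal_mortality(-1.0, 1.0, "linear", self.LINEAR)


class TestStep:
    def test_two_step_logistic_matches_hand_oracle(self):
        """Schaefer step: B' = B + r*B*(1-B/K) - F*B, computed by hand."""
        st_log = single_stock_logistic(r=0.5, K=100.0)
        state = StockState(
            adult={"cod": 50.0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        regime = {"cod": 0.1, "herring": 0.0, "sprat": 0.0}
        # year 1: P = 0.5*50*0.5 = 12.5, C = 5.0 -> B = 57.5
        state, rec1 = step(state, regime, UNIT_FORCING, st_log)
        assert rec1.catch["cod"] == pytest.approx(5.0, abs=1e-12)
        assert state.adult["cod"] == pytest.approx(57.5, abs=1e-12)
        # year 2: P = 0.5*57.5*0.425 = 12.21875, C = 5.75 -> B = 63.96875
        state, rec2 = step(state, regime, UNIT_FORCING, st_log)
        assert rec2.catch["cod"] == pytest.approx(5.75, abs=1e-12)
        assert state.adult["cod"] == pytest.approx(63.96875, abs=1e-12)

    def test_equilibrium_is_a_fixed_point(self):
        """Unfished logistic stock at carrying capacity stays put."""
        st_log = single_stock_logistic(r=0.5, K=100.0)
        state = StockState(
            adult={"cod": 100.0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        regime = {s: 0.0 for s in STOCKS}
        nxt, rec = step(state, regime, UNIT_FORCING, st_log)
        assert nxt.adult["cod"] == pytest.approx(100.0, abs=1e-12)
        assert rec.catch["cod"] == 0.0

    def test_full_harvest_removes_everything(self):
        """Harvest-rate F=1 with no production removes the whole pool."""
        st_log = single_stock_logistic(r=0.0, K=100.0)
        state = StockState(
            adult={"cod": 30.0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        regime = {"cod": 1.0, "herring": 0.0, "sprat": 0.0}
        nxt, rec = step(state, regime, UNIT_FORCING, st_log)
        assert rec.catch["cod"] == pytest.approx(30.0)
        assert nxt.adult["cod"] == 0.0
        assert rec.collapsed["cod"]

    def test_baranov_catch_closed_form(self):
        """Instantaneous convention follows the Baranov catch equation."""
        st_log = single_stock_logistic(r=0.0, K=100.0, f_convention="instantaneous")
        b0, f = 40.0, 0.7
        state = StockState(
            adult={"cod": b0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        nxt, rec = step(state, {"cod": f, "herring": 0, "sprat": 0}, UNIT_FORCING, st_log)
        # M = 0, so Z = F: C = (1 - e^-F) * B, survivors B e^-F
        assert rec.catch["cod"] == pytest.approx(b0 * (1 - math.exp(-f)), rel=1e-12)
        assert nxt.adult["cod"] == pytest.approx(b0 * math.exp(-f), rel=1e-12)

    def test_harvest_rate_rejects_f_above_one(self):
        st_log = single_stock_logistic(r=0.5, K=100.0)
        state = StockState(
            adult={"cod": 50.0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        with pytest.raises(RegimeError):
            step(state, {"cod": 1.2, "herring": 0, "sprat": 0}, UNIT_FORCING, st_log)
        with pytest.raises(RegimeError):
            step(state, {"cod": -0.1, "herring": 0, "sprat": 0}, UNIT_FORCING, st_log)

    def test_invalid_forcing_rejected(self):
        bad = ForcingYear(
            year=2014,
            growth_mult={"cod": float("nan"), "herring": 1.0, "sprat": 1.0},
            recruit_mult={s: 1.0 for s in STOCKS},
            seal_biomass=1.0,
        )
        st_log = single_stock_logistic(r=0.5, K=100.0)
        state = StockState(
            adult={"cod": 50.0, "herring": 0.0, "sprat": 0.0},
            juvenile={s: 0.0 for s in STOCKS},
        )
        with pytest.raises(ForcingError):
            step(state, {s: 0.0 for s in STOCKS}, bad, st_log)


class TestSimulate:
    def test_one_year_simulation_equals_one_step(self, ensemble):
        structure = ensemble["mspm_like"]
        forcing = make_forcing("BAU", "LSE", seed=5, years=np.arange(2014, 2015))
        baseline = gen_baseline(5)
        regime = {"cod": 0.3, "herring": 0.2, "sprat": 0.2}
        result = simulate(structure, regime, forcing, baseline)
        state = StockState.from_baseline(baseline)
        fy = ForcingYear.from_scenario(forcing, 2014)
        _, rec = step(state, regime, fy, structure)
        for s in STOCKS:
            assert result.ssb[s][0] == baseline.adult[s]
            assert result.catch[s][0] == pytest.approx(rec.catch[s], rel=1e-12)

    def test_unfished_unpredated_stock_yields_nothing(self, forcing, baseline, ensemble):
        """Cod has no predator in any variant: F=0 means zero cod catch."""
        result = simulate(
            ensemble["gadget_like"], {"cod": 0.0, "herring": 0.3, "sprat": 0.3},
            forcing, baseline,
        )
        assert np.all(result.catch["cod"] == 0.0)

    def test_nonnegativity_randomised_sweep(self, ensemble, baseline):
        """No state or catch ever goes negative across ~10^4 random regimes."""
        rng = np.random.default_rng(123)
        for name, structure in ensemble.items():
            forcing = make_forcing("BSAP", "HSE", seed=17)
            n = 3500
            fmax = min(structure.f_max, 1.4)
            f = rng.uniform(0, fmax, size=(n, 3))
            sim = simulate_grid(structure, f, forcing, baseline)
            for s in STOCKS:
                assert np.all(sim.ssb[s] >= 0), name
                assert np.all(sim.juvenile[s] >= 0), name
                assert np.all(sim.catch[s] >= 0), name

    def test_grid_and_single_run_agree(self, forcing, baseline, ensemble):
        structure = ensemble["ewe_like"]
        f = np.array([[0.4, 0.2, 0.6], [0.0, 0.0, 0.0]])
        sim = simulate_grid(structure, f, forcing, baseline)
        single = simulate(structure, {"cod": 0.4, "herring": 0.2, "sprat": 0.6},
                          forcing, baseline)
        for s in STOCKS:
            np.testing.assert_array_equal(sim.ssb[s][:, 0], single.ssb[s])
            np.testing.assert_array_equal(sim.catch[s][:, 0], single.catch[s])


def test_no_feedback_variant_cod_dynamics_ignore_clupeid_f(baseline):
    """Without prey-to-predator feedback or cannibalism, cod trajectories are
    bitwise identical across clupeid fishing mortalities."""
    gadget = [m for m in default_ensemble() if m.name == "gadget_like"][0]
    forcing = make_forcing("BAU", "HSE", seed=2)
    f = np.array([[0.5, a, b] for a in (0.0, 0.5, 1.0) for b in (0.0, 0.5, 1.0)])
    sim = simulate_grid(gadget, f, forcing, baseline)
    ref_ssb = sim.ssb["cod"][:, 0]
    ref_catch = sim.catch["cod"][:, 0]
    for j in range(f.shape[0]):
        np.testing.assert_array_equal(sim.ssb["cod"][:, j], ref_ssb)
        np.testing.assert_array_equal(sim.catch["cod"][:, j], ref_catch)
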
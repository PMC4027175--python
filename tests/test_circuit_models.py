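"""Right-hand sides, the simulation driver, and cross-model consistency."""

import numpy as np
import pytest

from iffl import (CircuitConfig, InputSchedule, RateParams, SimOptions,
                  derived_rates, equilibrium_simple, simulate)
from iffl.circuit_models import (mm_saturation, rhs_detailed, rhs_mm,
                                 rhs_nondim, rhs_simple)
from iffl.params import DerivedRates


def unit_dr():
    return DerivedRates(alpha1=1.0, alpha2=1.0, beta1_eff=1.0, gamma1_eff=1.0)


class TestSimpleRhs:
    def test_equilibrium_annihilates_rhs(self, rates_noburst, config):
        dr = derived_rates(config, rates_noburst)
        eq = equilibrium_simple(dr, rates_noburst.k, u=20.0)
        d = rhs_simple(eq.as_array(), 20.0, dr, rates_noburst.k)
        assert np.allclose(d, 0.0, atol=1e-15)

    def test_zero_state_zero_input(self):
        assert rhs_simple((0, 0, 0), 0.0, unit_dr(), 1.0) == (0.0, 0.0, 0.0)

    def test_direct_substitution(self):
        # alpha1=alpha2=beta1=gamma1=k=1, u=2, x=y=z=1
        assert rhs_simple((1, 1, 1), 2.0, unit_dr(), 1.0) == (1.0, 1.0, 0.0)

    def test_imgs_are_recycled_not_destroyed(self):
        """x + z production/loss balance carries no complex-degradation term:
        degrading rMG inside the complex returns the iMG strand."""
        state, u, k = (3.0, 2.0, 5.0), 7.0, 0.8
        sums = []
        for gamma in (0.0, 10.0):
            dr = DerivedRates(alpha1=1.2, alpha2=0.7, beta1_eff=0.4,
                              gamma1_eff=gamma)
            dx, _, dz = rhs_simple(state, u, dr, k)
            sums.append(dx + dz)
        assert sums[0] == pytest.approx(sums[1])
        assert sums[0] == pytest.approx(1.2 * u - 0.4 * state[0])


class TestMichaelisMenten:
    def test_half_saturation(self):
        r = RateParams(kp1=1, kp2=1, k=1, beta1=1, gamma1=1,
                       K_M=50.0, K_M_R_x=20.0, K_M_R_z=30.0)
        f, g = mm_saturation(50.0, 20.0, 0.0, r)
        assert f == pytest.approx(0.5)
        assert g == pytest.approx(0.5)

    def test_zero_substrates_no_saturation(self):
        r = RateParams(kp1=1, kp2=1, k=1, beta1=1, gamma1=1)
        assert mm_saturation(0.0, 0.0, 0.0, r) == (1.0, 1.0)

    @pytest.mark.parametrize("km,tol", [(1e6, 1e-4), (1e8, 1e-6)])
    def test_large_km_recovers_first_order_kinetics(self, km, tol):
        """Relative derivative deviation scales as (concentration / K_M)."""
        r = RateParams(kp1=1, kp2=1, k=0.5, beta1=0.3, gamma1=0.4,
                       K_M=km, K_M_R_x=km, K_M_R_z=km)
        dr = DerivedRates(alpha1=0.6, alpha2=0.4, beta1_eff=0.3, gamma1_eff=0.4)
        state, u = (5.0, 1.0, 3.0), 20.0
        a = np.array(rhs_simple(state, u, dr, r.k))
        b = np.array(rhs_mm(state, u, dr, r))
        denom = np.maximum(np.abs(a), 1e-12)
        assert np.max(np.abs(a - b) / denom) < 100 * tol

    def test_nonpositive_michaelis_constant_rejected(self):
        with pytest.raises(ValueError):
            RateParams(kp1=1, kp2=1, k=1, beta1=1, gamma1=1, K_M=0.0)


class TestNondimRhs:
    def test_normalized_steady_state(self):
        assert rhs_nondim((1, 1, 1), 1.0, 0.2, 5.0, 0.6) == (0.0, 0.0, 0.0)

    def test_step_substitution(self):
        p1, p2, p3 = 0.3, 4.0, 0.7
        assert rhs_nondim((1, 1, 1), 2.0, p1, p2, p3) == (1.0, p2, 0.0)

    @pytest.mark.parametrize("state", [(2, 1, 1), (1, 0.5, 2), (0.3, 3, 0.9)])
    def test_complex_flux_sign_follows_mass_action(self, state):
        x, y, z = state
        _, _, dz = rhs_nondim(state, 1.0, 0.2, 1.0, 0.6)
        assert np.sign(dz) == np.sign(x * y - z)


class TestDetailedModel:
    def test_no_activator_no_production(self, rates, config):
        d = rhs_detailed((0, 0, 0, 0, 0), 0.0, rates, config)
        assert d == (0, 0, 0, 0, 0)

    def test_conservation_violation_raises(self, rates, config):
        from iffl.circuit_models import SimulationError
        with pytest.raises(SimulationError):
            rhs_detailed((30, 30, 0, 0, 0), 10.0, rates, config)

    def test_fast_binding_consumes_free_activator(self, rates, config,
                                                  step_schedule):
        # templates in excess of activator: free A -> 0 for fast k_plus
        tr = simulate("detailed", rates.replace(k_plus=10.0), config,
                      step_schedule, SimOptions(t_end=30.0, grid_dt=0.5))
        free_a = tr["u"] - tr["TiA"] - tr["TrA"]
        assert free_a[-1] < 1e-3 * 20.0

    def test_matches_simple_model_for_fast_binding(self, rates_noburst,
                                                   config, step_schedule):
        opts = SimOptions(t_end=400.0, grid_dt=1.0)
        tr_s = simulate("simple", rates_noburst, config, step_schedule, opts)
        tr_d = simulate("detailed", rates_noburst.replace(k_plus=10.0),
                        config, step_schedule, opts)
        diff = np.max(np.abs(np.interp(tr_s.t, tr_d.t, tr_d["y"]) - tr_s["y"]))
        assert diff < 0.01 * tr_s["y"].max()


class TestSimulate:
    def test_empty_schedule_zero_initial_state_stays_zero(self, rates, config):
        tr = simulate("simple", rates, config, InputSchedule(),
                      SimOptions(t_end=60.0, grid_dt=1.0))
        for name in ("x", "y", "z"):
            assert np.allclose(tr[name], 0.0, atol=1e-12)

    def test_equilibrium_initial_state_is_stationary(self, rates_noburst, config):
        dr = derived_rates(config, rates_noburst)
        eq = equilibrium_simple(dr, rates_noburst.k, 20.0)
        tr = simulate("simple", rates_noburst, config,
                      InputSchedule(((0.0, "A", 20.0),)),
                      SimOptions(t_end=300.0, grid_dt=1.0),
                      initial_state=eq.as_array())
        assert np.allclose(tr["y"], eq.y_bar, rtol=1e-6)

    def test_step_input_pulses_and_adapts(self, rates_noburst, config):
        """Doubling the input produces a transient pulse in the output that
        returns to the pre-step steady level (exact adaptation)."""
        sched = InputSchedule(((0.0, "A", 20.0), (600.0, "A", 20.0)))
        tr = simulate("simple", rates_noburst, config, sched,
                      SimOptions(t_end=1800.0, grid_dt=1.0))
        dr = derived_rates(config, rates_noburst)
        ybar = equilibrium_simple(dr, rates_noburst.k, 20.0).y_bar
        pre = tr["y"][tr.t == 600.0][0]
        post_peak = tr["y"][tr.t > 600].max()
        final = tr["y"][-1]
        assert pre == pytest.approx(ybar, rel=1e-5)
        assert post_peak > 1.2 * ybar          # a visible pulse
        assert final == pytest.approx(pre, rel=1e-4)  # back in the band

    def test_event_times_are_sample_points(self, rates, config):
        sched = InputSchedule(((0.0, "A", 10.0), (33.33, "A", 10.0)))
        tr = simulate("simple", rates, config, sched,
                      SimOptions(t_end=100.0, grid_dt=1.0))
        assert np.any(np.isclose(tr.t, 33.33))

    def test_trajectories_stay_nonnegative(self, rates, config):
        sched = InputSchedule(((0.0, "A", 40.0), (200.0, "I", 35.0)))
        tr = simulate("simple", rates, config, sched,
                      SimOptions(t_end=600.0, grid_dt=0.5))
        for name in ("x", "y", "z"):
            assert tr[name].min() >= -1e-9

    def test_unknown_model_kind_rejected(self, rates, config):
        with pytest.raises(ValueError):
            simulate("bogus", rates, config)
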
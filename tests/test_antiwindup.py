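"""Anti-windup topologies: switch shapes, CRN loops, conditional
integration, conditioning factors and windup metrics."""

import numpy as np
import pytest

from antithetic import (
    AIFParams,
    GeneExpressionProcess,
    ReducedAWParams,
    SaturationFunctions,
    SequestrationSwitch,
    TopologyParams,
    aif_loop,
    conditioning_factors,
    hill_repression,
    linear_above_threshold,
    phenomenological_loop,
    reduced_aif_loop,
    reduced_conditional_integration_loop,
    steady_state_error,
    topology_loop,
    windup_metrics,
)
from antithetic.crn import Trajectory, ValidationError, find_steady_state
from antithetic.switches import _SwitchSystem


@pytest.fixture
def sat_process():
    return GeneExpressionProcess(delta=5.0)


def topo(kind, params, sats, **kw):
    defaults = dict(v0=10.0, w0=20.0, eta_v=100.0, eta_w=100.0)
    defaults.update(kw)
    return TopologyParams(topology=kind, aif=params, sats=sats, **defaults)


class TestSwitchShapes:
    def test_linear_above_threshold_is_continuous_ramp(self):
        h = linear_above_threshold(2.0, 5.0)
        assert h(4.0) == 0.0
        assert h(5.0) == 0.0
        assert h(6.5) == pytest.approx(3.0)

    def test_hill_repression_half_point(self):
        h = hill_repression(10.0, 4.0)
        assert h(0.0) == 10.0
        assert h(4.0) == 5.0
        assert h(1e9) < 1e-7 * 10.0

    def test_invalid_kinds_rejected(self):
        from antithetic.antiwindup import SwitchShape
        with pytest.raises(ValidationError):
            SwitchShape("step", 1.0, 1.0)


class TestTopologyLoops:
    def test_disabled_switches_reduce_to_base_controller(self, sat_process,
                                                         sat_params, sat_sats,
                                                         rng):
        p = topo("I", sat_params, sat_sats,
                 h1=lambda s: 0.0, h2=lambda s: 0.0)
        loop_aw = topology_loop(p, sat_process)
        loop_base = aif_loop(sat_process, sat_params, sat_sats)
        for _ in range(50):
            s = rng.uniform(0, 25, size=8)
            ds_aw = loop_aw.rhs(0.0, s)
            ds_base = loop_base.rhs(0.0, s[:4])
            assert np.allclose(ds_aw[:4], ds_base, atol=1e-12)

    def test_topology_II_quadratic_degradation_in_the_strong_limit(self):
        # steady-state degradation propensity h1(v2bar)*z1 with
        # v2bar = max(z1 - v0, 0)/delta: quadratic c*(v0 + c) beyond threshold
        sw = SequestrationSwitch(u0=10.0, eta_v=1e4)
        for c in (2.0, 5.0):
            z1 = sw.u0 + c
            res = find_steady_state(_SwitchSystem(sw, z1), [0.0, 0.0])
            propensity = res.state[1] * z1
            assert propensity == pytest.approx(c * (sw.u0 + c), rel=5e-3)

    def test_topology_II_below_threshold_has_no_degradation(self):
        sw = SequestrationSwitch(u0=10.0, eta_v=1e4)
        res = find_steady_state(_SwitchSystem(sw, 7.0), [0.0, 0.0])
        assert res.state[1] * 7.0 < 0.01

    def test_topology_III_production_halves_at_kappa(self, sat_params,
                                                     sat_sats, sat_process):
        p = topo("III", sat_params, sat_sats, kappa1=3.0)
        loop = topology_loop(p, sat_process)
        # production term of z1 is h1(v2) = mu/(1 + v2/kappa1)
        assert p.h1(0.0) == sat_params.mu
        assert p.h1(3.0) == sat_params.mu / 2.0
        # at v2 = 0 the z1 balance matches the base AIF
        s = np.zeros(8)
        s[2:4] = [2.0, 1.0]
        base = aif_loop(sat_process, sat_params, sat_sats)
        assert loop.rhs(0.0, s)[2] == pytest.approx(base.rhs(0.0, s[:4])[2])

    def test_topology_III_bounds_the_integrator_under_saturating_demand(
            self, sat_sats, sat_process):
        # setpoint demand beyond the admissible band: the bare loop winds
        # z1 up without bound, topology III keeps it bounded
        params = AIFParams(mu=12.0, theta=15.0, eta=100.0, k=8.0)
        base = aif_loop(sat_process, params, sat_sats)
        p = topo("III", params, sat_sats)
        protected = topology_loop(p, sat_process)
        t_eval = np.linspace(0.0, 200.0, 401)
        z1_base = base.simulate((0, 200), t_eval=t_eval).species("z1").max()
        z1_prot = protected.simulate((0, 200), t_eval=t_eval).species("z1").max()
        assert z1_base > 100.0
        assert z1_prot < 30.0

    def test_mismatched_topology_params_rejected(self, sat_params, sat_sats,
                                                 sat_process):
        from antithetic.antiwindup import topology_I_loop
        with pytest.raises(ValidationError):
            topology_I_loop(topo("II", sat_params, sat_sats), sat_process)


class TestRPAPreservation:
    def test_phenomenological_switches_preserve_rpa_exactly(self, sat_params,
                                                            sat_sats,
                                                            sat_process):
        # below threshold the shapes output exactly zero, so the protected
        # loop shares the base loop's fixed point
        ph = phenomenological_loop(
            "I", sat_process, sat_params,
            linear_above_threshold(1.0, 10.0), linear_above_threshold(1.0, 20.0),
            sat_sats)
        base = aif_loop(sat_process, sat_params, sat_sats)
        y_ph = ph.output(ph.steady_state(t_max=3000.0).state)
        y_base = base.output(base.steady_state(t_max=3000.0).state)
        assert abs(y_ph - y_base) < 1e-6

    def test_crn_switch_leak_shrinks_like_inverse_eta(self, sat_params,
                                                      sat_sats, sat_process):
        # finite switch sequestration leaks a small Z2 production that
        # offsets the output; the offset scales as 1/eta_w
        base = aif_loop(sat_process, sat_params, sat_sats)
        y_base = base.output(base.steady_state(t_max=3000.0).state)
        gaps = []
        for eta in (100.0, 1000.0):
            p = topo("I", sat_params, sat_sats, eta_v=eta, eta_w=eta)
            loop = topology_loop(p, sat_process)
            y = loop.output(loop.steady_state(t_max=3000.0).state)
            gaps.append(abs(y - y_base))
        assert gaps[0] < 0.05          # small on the output scale of 10
        assert gaps[1] < 0.2 * gaps[0]  # 10x eta -> ~10x smaller offset


class TestConditionalIntegration:
    def params(self, r_in=2.0 / 3.0, topology="I"):
        return ReducedAWParams(KI=120.0, k=8.0, alpha1=1.0, alpha2=1.0,
                               beta1=10.0, beta2=20.0, theta=15.0,
                               r_in=r_in, topology=topology)

    def test_middle_branch_equals_pure_integral_loop(self, sat_process,
                                                     sat_sats):
        p = self.params()
        cond = reduced_conditional_integration_loop(p, sat_process, sat_sats)
        pure = reduced_aif_loop(sat_process,
                                AIFParams(mu=10.0, theta=15.0, eta=1.0, k=8.0),
                                sat_sats)
        t_eval = np.linspace(0.0, 60.0, 301)
        tc = cond.simulate((0, 60), t_eval=t_eval)
        tp = pure.simulate((0, 60), t_eval=t_eval)
        assert tc.species("v").max() < p.band[1]  # never leaves the band
        assert np.allclose(tc.species("v"), p.k * tp.species("z"), atol=1e-6)
        assert np.allclose(tc.species("x2"), tp.species("x2"), atol=1e-6)

    def test_band_assignment_follows_topology(self):
        pI = self.params(topology="I")
        pII = self.params(topology="II")
        assert pI.band == (-8.0 * 10.0, 8.0 * 20.0)
        assert pII.band == (-8.0 * 20.0, 8.0 * 10.0)

    def test_vanishing_leak_recovers_pure_integrator(self):
        p = ReducedAWParams(KI=120.0, k=8.0, alpha1=1e-12, alpha2=1e-12,
                            beta1=10.0, beta2=20.0, theta=15.0, r_in=0.8)
        # far outside the band the drift is still ~KI*e
        assert p.vdot(0.5, 500.0) == pytest.approx(120.0 * 0.5, abs=1e-6)

    @pytest.mark.parametrize("r_in", [0.8, 0.45])
    def test_long_run_error_matches_the_leak_formula(self, r_in, sat_process,
                                                     sat_sats):
        p = self.params(r_in=r_in)
        loop = reduced_conditional_integration_loop(p, sat_process, sat_sats)
        res = loop.steady_state(t_max=5000.0)
        assert res.converged
        v_bar = res.state[-1]
        e_sim = p.r_in - sat_sats.hs(loop.output(res.state))
        assert e_sim == pytest.approx(steady_state_error(v_bar, p), abs=1e-6)


class TestSteadyStateError:
    def test_zero_inside_the_band(self):
        p = ReducedAWParams(KI=1.0, k=1.0, alpha1=1.0, alpha2=1.0,
                            beta1=2.0, beta2=3.0, theta=1.0, r_in=1.0)
        for v in (-2.0, 0.0, 3.0):
            assert steady_state_error(v, p) == 0.0

    def test_unit_slope_when_leak_equals_gain(self):
        p = ReducedAWParams(KI=5.0, k=1.0, alpha1=1.0, alpha2=5.0,
                            beta1=2.0, beta2=3.0, theta=1.0, r_in=1.0)
        # above the band (j=2): e = (alpha2/KI)*(v - k*beta2) = v - 3
        assert steady_state_error(4.0, p) == pytest.approx(1.0)

    def test_continuity_at_band_edges(self):
        p = ReducedAWParams(KI=2.0, k=3.0, alpha1=1.5, alpha2=0.5,
                            beta1=2.0, beta2=3.0, theta=1.0, r_in=1.0)
        lo, hi = p.band
        eps = 1e-12
        assert steady_state_error(hi, p) == 0.0
        assert abs(steady_state_error(hi + eps, p)) < 1e-9
        assert steady_state_error(lo, p) == 0.0
        assert abs(steady_state_error(lo - eps, p)) < 1e-9


class TestReductionConsistency:
    def test_switch_pairs_reduce_to_the_conditional_integration_law(self, rng):
        """Reducing both topology-I switch pairs (identity inputs/readouts,
        unit degradation) turns the integrator-output dynamics into exactly
        the piecewise conditional-integration law with alpha = 1/delta and
        beta = threshold."""
        k, theta, mu = 8.0, 15.0, 10.0
        v0, w0 = 10.0, 20.0
        p = ReducedAWParams(KI=k * theta, k=k, alpha1=1.0, alpha2=1.0,
                            beta1=v0, beta2=w0, theta=theta, r_in=mu / theta,
                            topology="I")
        hs = SaturationFunctions.hill_pair(5.0, 5.0).hs
        for _ in range(1000):
            z = rng.uniform(-40, 40)
            y = rng.uniform(0, 20)
            zp, zn = max(z, 0.0), max(-z, 0.0)
            # reduced switch outputs: red sees z2 = zn, blue sees z1 = zp
            h1 = max(zn - v0, 0.0)
            h2 = max(zp - w0, 0.0)
            drift = (mu + h1) - (theta * hs(y) + h2)
            e = mu / theta - hs(y)
            assert k * drift == pytest.approx(p.vdot(e, k * z), abs=1e-8)


class TestConditioningFactors:
    def params(self):
        return ReducedAWParams(KI=1.0, k=2.0, alpha1=3.0, alpha2=4.0,
                               beta1=5.0, beta2=6.0, theta=1.0, r_in=1.0)

    def test_unity_inside_the_band(self):
        p = self.params()
        assert conditioning_factors(p.k * p.beta1, p) == (1.0, 1.0)
        assert conditioning_factors(0.0, p) == (1.0, 1.0)
        assert conditioning_factors(-p.k * p.beta2, p) == (1.0, 1.0)

    def test_half_conditioning_points(self):
        p = self.params()
        rho_ref, _ = conditioning_factors(p.k * (p.beta1 + p.alpha1), p)
        assert rho_ref == pytest.approx(0.5)
        _, rho_sense = conditioning_factors(-p.k * (p.beta2 + p.alpha2), p)
        assert rho_sense == pytest.approx(0.5)

    def test_factors_stay_in_unit_interval(self, rng):
        p = self.params()
        for v in rng.uniform(-1e4, 1e4, size=200):
            rho_ref, rho_sense = conditioning_factors(v, p)
            assert 0.0 < rho_ref <= 1.0
            assert 0.0 < rho_sense <= 1.0


class TestWindupMetrics:
    def _traj(self, t, z):
        return Trajectory(t, z[:, None], ["z2"])

    def test_quiet_trajectory_has_null_metrics(self):
        t = np.linspace(0, 10, 101)
        traj = self._traj(t, np.zeros_like(t))
        rep = windup_metrics(traj, controller_species=["z2"], threshold=1.0,
                             error=np.zeros_like(t), setpoint=10.0,
                             disturbance_window=(2.0, 4.0))
        assert rep.peaks["z2"] == 0.0
        assert rep.time_above_threshold["z2"] == 0.0
        assert rep.recovery_time == 0.0

    def test_transient_crossing_does_not_count_as_recovery(self):
        t = np.linspace(0, 10, 1001)
        # error crosses zero at t=5 but only stays inside the band from t=8
        error = np.where(t < 5, 5.0, np.where(t < 8, -2.0, 0.1))
        traj = self._traj(t, np.zeros_like(t))
        rep = windup_metrics(traj, controller_species=["z2"], threshold=1.0,
                             error=error, setpoint=10.0,
                             disturbance_window=(0.0, 4.0))
        assert rep.recovery_time == pytest.approx(4.0, abs=0.05)

    def test_unmarked_disturbance_window_rejected(self):
        t = np.linspace(0, 1, 11)
        traj = self._traj(t, np.zeros_like(t))
        with pytest.raises(ValidationError, match="window"):
            windup_metrics(traj, controller_species=["z2"], threshold=1.0,
                           error=np.zeros_like(t), setpoint=1.0,
                           disturbance_window=None)
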
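import math

import numpy as np
import pytest

from cfvadsim import (
    BaroreflexParams,
    CirculationState,
    baroreflex_targets,
    total_blood_volume,
    valve_flow,
)
from cfvadsim import _core
from cfvadsim.circulatory_network import N_STATES, STATE_NAMES, derivatives
from cfvadsim.heart_chambers import activation, edp_envelope, esp_envelope
from conftest import make_demo_scenario


class TestValveFlow:
    def test_equal_pressures_give_zero_flow(self):
        assert valve_flow(10.0, 10.0, 0.01) == 0.0

    def test_ohmic_forward_flow(self):
        assert valve_flow(100.0, 80.0, 0.05) == pytest.approx(400.0)

    def test_no_regurgitation(self):
        assert valve_flow(80.0, 100.0, 0.05) == 0.0

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            valve_flow(10.0, 0.0, 0.0)


class TestBaroreflexTargets:
    def test_setpoint_gives_nominal_effectors(self):
        bp = BaroreflexParams()
        tg = baroreflex_targets(bp.P_set, bp)
        assert tg.r_scale == pytest.approx(1.0)
        assert tg.vu_shift == pytest.approx(0.0)
        assert tg.contractility == pytest.approx(1.0)

    def test_negative_feedback_signs(self):
        bp = BaroreflexParams()
        hi = baroreflex_targets(bp.P_set + 20.0, bp)
        lo = baroreflex_targets(bp.P_set - 20.0, bp)
        # hypertension: vasodilate, venodilate, reduce contractility
        assert hi.r_scale < 1.0 < lo.r_scale
        assert hi.vu_shift > 0.0 > lo.vu_shift
        assert hi.contractility < 1.0 < lo.contractility

    def test_first_order_effector_response(self):
        """Effector relaxes to a stepped target with its own time constant."""
        sc = make_demo_scenario()
        bp = sc.baroreflex
        tg = baroreflex_targets(bp.P_set + 20.0, bp).r_scale
        # integrate dx/dt = (tg - x)/tau with x(0)=1 over 4 tau, forward Euler
        x, dt = 1.0, 1e-3
        n = int(4.0 * bp.tau_R / dt)
        for _ in range(n):
            x += dt * (tg - x) / bp.tau_R
        expected = tg + (1.0 - tg) * math.exp(-4.0)
        assert x == pytest.approx(expected, rel=2e-2)
        assert abs(x - tg) < 0.02 * abs(1.0 - tg)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            baroreflex_targets(0.0, BaroreflexParams())


def _pump_free_oracle(state, t, sc):
    """Independently coded pump-free network derivative (exact diodes).

    Recomputes every flow and balance from scratch with scipy root finding
    for the septal displacement; deliberately shares no code with the
    package's derivative path beyond the constitutive envelope formulas.
    """
    from scipy.optimize import brentq

    vp, bp = sc.vascular, sc.baroreflex
    T = 60.0 / vp.heart_rate
    tc = t % T
    e = activation(tc, T, sc.lv.Ts_frac)
    import dataclasses

    lv = dataclasses.replace(sc.lv, lambda_asc=sc.lv.lambda_asc * state.x_emax,
                             P_int=None)
    rv = dataclasses.replace(sc.rv, lambda_asc=sc.rv.lambda_asc * state.x_emax,
                             P_int=None)

    def sys_env(V, p):
        # systolic envelope never below the passive curve
        return max(esp_envelope(V, p), edp_envelope(V, p))

    def chamber_p(V, p):
        return e * sys_env(V, p) + (1 - e) * edp_envelope(V, p)

    E_spt = e * sc.septum.Es_sys + (1 - e) * sc.septum.Es_dia

    def g(x):
        return E_spt * x - (chamber_p(state.V_lv - x, lv)
                            - chamber_p(state.V_rv + x, rv))

    v_spt = brentq(g, -0.6 * state.V_rv, 0.6 * state.V_lv, xtol=1e-12)
    P_lv_sup = chamber_p(state.V_lv - v_spt, lv)
    P_rv_sup = chamber_p(state.V_rv + v_spt, rv)
    Rv_l = lv.Rv_coeff * e * sys_env(state.V_lv - v_spt, lv)
    Rv_r = rv.Rv_coeff * e * sys_env(state.V_rv + v_spt, rv)

    # aortic valve: diode in series with the ejection resistance
    Q_aov = max(P_lv_sup - state.P_sa, 0.0) / (vp.R_aortic + Rv_l)
    P_lv = P_lv_sup - Rv_l * Q_aov
    Q_mi = max(state.P_pv - P_lv, 0.0) / vp.R_mitral
    Q_pov = max(P_rv_sup - state.P_pa, 0.0) / (vp.R_pulmonic + Rv_r)
    P_rv = P_rv_sup - Rv_r * Q_pov
    Q_ti = max(state.P_sv - P_rv, 0.0) / vp.R_tricuspid

    s = 1.0 / (1.0 + math.exp((state.P_sa - bp.P_set) / bp.k_s))
    g_r = bp.g_R_hypo if s > 0.5 else bp.g_R_hyper
    dx_rsp = (1 + g_r * (2 * s - 1) - state.x_rsp) / bp.tau_R
    dx_vu = (bp.Vu_span * (0.5 - s) - state.x_vu) / bp.tau_Vu
    dx_emax = (1 + bp.g_E * (2 * s - 1) - state.x_emax) / bp.tau_E

    Q_sp = (state.P_sp - state.P_sv) / (vp.R_sp * state.x_rsp)
    Q_pp = (state.P_pp - state.P_pv) / vp.R_pp
    return np.array([
        Q_mi - Q_aov,
        Q_ti - Q_pov,
        (Q_aov - state.Q_sa) / vp.C_sa,
        (state.P_sa - state.P_sp - vp.R_sa * state.Q_sa) / vp.L_sa,
        (state.Q_sa - Q_sp) / vp.C_sp,
        (Q_sp - Q_ti - dx_vu) / vp.C_sv,
        (Q_pov - state.Q_pa) / vp.C_pa,
        (state.P_pa - state.P_pp - vp.R_pa * state.Q_pa) / vp.L_pa,
        (state.Q_pa - Q_pp) / vp.C_pp,
        (Q_pp - Q_mi) / vp.C_pv,
        0.0, dx_rsp, dx_vu, dx_emax,
    ])


def _random_states(rng, n):
    for _ in range(n):
        yield CirculationState(
            V_lv=rng.uniform(40, 300), V_rv=rng.uniform(40, 300),
            P_sa=rng.uniform(60, 140), Q_sa=rng.uniform(-50, 400),
            P_sp=rng.uniform(50, 120), P_sv=rng.uniform(1, 15),
            P_pa=rng.uniform(10, 60), Q_pa=rng.uniform(-50, 400),
            P_pp=rng.uniform(5, 40), P_pv=rng.uniform(2, 30),
            Q_vad=rng.uniform(-50, 200),
            x_rsp=rng.uniform(0.85, 1.15), x_vu=rng.uniform(-200, 200),
            x_emax=rng.uniform(0.85, 1.15),
        )


class TestDerivatives:
    def test_constructed_equilibrium_has_zero_derivatives(self):
        """A direct solve of the rest state leaves residuals below 1e-10."""
        sc = make_demo_scenario()
        bp = sc.baroreflex
        P = bp.P_set
        # diastolic instant, all compartment pressures equal, chambers at
        # the volume whose passive pressure equals P, effectors nominal
        t = 0.9 * sc.vascular.period
        V_lv = sc.lv.V0 + math.log(P / sc.lv.A_ed + 1.0) / sc.lv.B_ed
        V_rv = sc.rv.V0 + math.log(P / sc.rv.A_ed + 1.0) / sc.rv.B_ed
        st = CirculationState(V_lv=V_lv, V_rv=V_rv, P_sa=P, Q_sa=0.0,
                              P_sp=P, P_sv=P, P_pa=P, Q_pa=0.0, P_pp=P,
                              P_pv=P, Q_vad=0.0)
        dy = derivatives(st, t, sc, 0.0, pump_connected=False, diode_eps=0.0)
        assert np.max(np.abs(dy)) < 1e-10

    def test_mass_conservation_at_every_evaluation(self, rng):
        """Sum of all volume rates (incl. unstressed-volume shift) is zero."""
        sc = make_demo_scenario()
        vp = sc.vascular
        C = np.array([1, 1, vp.C_sa, 0, vp.C_sp, vp.C_sv, vp.C_pa, 0,
                      vp.C_pp, vp.C_pv, 0, 0, 1, 0], dtype=float)
        for st in _random_states(rng, 25):
            t = rng.uniform(0, vp.period)
            dy = derivatives(st, t, sc, rpm_to_rad_safe(9000.0),
                             pump_connected=True, diode_eps=0.01)
            # pump flow moves volume LV -> aorta inside the loop: net zero
            assert abs(np.dot(C, dy)) < 1e-9

    def test_matches_pump_free_oracle_on_random_states(self, rng):
        """Full derivative with the pump branch removed equals an
        independently coded pump-free network."""
        sc = make_demo_scenario()
        for st in _random_states(rng, 30):
            t = rng.uniform(0, sc.vascular.period)
            got = derivatives(st, t, sc, 0.0, pump_connected=False,
                              diode_eps=0.0)
            ref = _pump_free_oracle(st, t, sc)
            assert np.allclose(got, ref, rtol=1e-8, atol=1e-8), (
                np.max(np.abs(got - ref)))

    def test_compiled_core_matches_reference(self, rng):
        """The JIT core and the readable reference stay in lockstep."""
        sc = make_demo_scenario()
        for connected in (True, False):
            pp = _core.pack_params(sc, 900.0, connected, 0.01)
            for st in _random_states(rng, 30):
                t = rng.uniform(0, sc.vascular.period)
                ref = derivatives(st, t, sc, 900.0, pump_connected=connected,
                                  diode_eps=0.01)
                got = _core.rhs(t, st.as_array(), pp)
                assert np.allclose(got, ref, rtol=1e-9, atol=1e-9)

    def test_nonfinite_state_raises_diagnostic(self):
        sc = make_demo_scenario()
        st = CirculationState(V_lv=float("nan"), V_rv=100, P_sa=90, Q_sa=0,
                              P_sp=85, P_sv=5, P_pa=20, Q_pa=0, P_pp=15,
                              P_pv=8)
        with pytest.raises(FloatingPointError, match="V_lv"):
            derivatives(st, 0.0, sc, 0.0)


def rpm_to_rad_safe(rpm):
    from cfvadsim import rpm_to_rad

    return rpm_to_rad(rpm)


class TestCirculationState:
    def test_array_round_trip(self, rng):
        y = rng.uniform(0, 100, N_STATES)
        st = CirculationState.from_array(y)
        assert np.allclose(st.as_array(), y)
        assert len(STATE_NAMES) == N_STATES == 14

    def test_total_blood_volume_accounting(self):
        sc = make_demo_scenario()
        from cfvadsim import initial_state

        st = initial_state(sc)
        assert total_blood_volume(st, sc.vascular) == pytest.approx(
            sc.vascular.total_blood_volume, abs=1e-8)
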
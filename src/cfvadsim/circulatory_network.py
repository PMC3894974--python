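"""Closed-loop vascular network, valves and baroreflex.

Electrical-analog lumped circulation: systemic and pulmonary circuits each
with an arterial compartment (compliance + inertance + proximal resistance),
a peripheral compartment and a venous reservoir; the atria are merged into
the respective venous reservoirs.  The four heart valves are ideal diodes.
Kirchhoff's laws over this network plus the two ventricular volumes, the
pump flow and three baroreflex effector states give the full state vector.

Arterial pressure is regulated by a sigmoid-afferent baroreflex whose
first-order effectors modulate systemic peripheral resistance, venous
unstressed volume and ventricular contractility; heart rate is held at the
configured value (the effector is clamped).

This module is the readable reference implementation of the model equations;
the simulation engine runs a compiled equivalent that is verified against
``derivatives`` in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, NamedTuple

import numpy as np

from .heart_chambers import (
    activation,
    edp_envelope,
    systolic_envelope,
    viscous_resistance,
)
from .septal_coupling import partition_volumes, solve_septal_volume
from .vad import pump_flow_derivative, suction_resistance

if TYPE_CHECKING:  # pragma: no cover
    from .simulation_engine import ScenarioConfig


@dataclass
class VascularParams:
    """Vascular compartment constants (mmHg, mL, s units) and global settings.

    Resistances in mmHg*s/mL, compliances in mL/mmHg, inertances in
    mmHg*s^2/mL, volumes in mL, heart rate in beats/min.
    """

    # valve resistances
    R_mitral: float
    R_aortic: float
    R_tricuspid: float
    R_pulmonic: float
    # systemic arterial
    C_sa: float
    R_sa: float
    L_sa: float
    Vu_sa: float
    # systemic peripheral
    C_sp: float
    R_sp: float
    Vu_sp: float
    # systemic venous (merged right atrium)
    C_sv: float
    Vu_sv: float
    # pulmonary arterial
    C_pa: float
    R_pa: float
    L_pa: float
    Vu_pa: float
    # pulmonary peripheral
    C_pp: float
    R_pp: float
    Vu_pp: float
    # pulmonary venous (merged left atrium)
    C_pv: float
    Vu_pv: float
    total_blood_volume: float
    heart_rate: float

    def __post_init__(self) -> None:
        for name in (
            "R_mitral", "R_aortic", "R_tricuspid", "R_pulmonic",
            "C_sa", "R_sa", "C_sp", "R_sp", "C_sv", "C_pa", "R_pa",
            "C_pp", "R_pp", "C_pv", "L_sa", "L_pa",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.total_blood_volume > 0:
            if self.unstressed_volume >= self.total_blood_volume:
                raise ValueError(
                    "sum of unstressed volumes must be < total blood volume"
                )
        elif self.unstressed_volume > 0 or self.total_blood_volume < 0:
            raise ValueError("empty system requires zero unstressed volumes")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be > 0")

    @property
    def unstressed_volume(self) -> float:
        return (
            self.Vu_sa + self.Vu_sp + self.Vu_sv
            + self.Vu_pa + self.Vu_pp + self.Vu_pv
        )

    @property
    def period(self) -> float:
        """Cardiac period (s)."""
        return 60.0 / self.heart_rate


@dataclass
class BaroreflexParams:
    """Sigmoid-afferent baroreflex with first-order effectors.

    The afferent signal s = 1/(1 + exp((P - P_set)/k_s)) rises toward 1 with
    hypotension.  Effector targets:

    * systemic peripheral resistance scale: 1 + g_R*(2s - 1), with separate
      gains below (g_R_hypo, vasoconstriction reserve) and above
      (g_R_hyper, vasodilation reserve) the setpoint — the sympathetic arm
      is much stronger than its withdrawal, as in Ursino-type asymmetric
      effector sigmoids
    * ventricular contractility scale:      1 + g_E*(2s - 1)
    * venous unstressed-volume shift (mL):  Vu_span*(0.5 - s)

    each approached exponentially with its own time constant.
    """

    P_set: float = 95.0
    k_s: float = 11.0
    g_R_hypo: float = 0.62
    g_R_hyper: float = 0.18
    g_E: float = 0.15
    Vu_span: float = 700.0
    tau_R: float = 6.0
    tau_Vu: float = 20.0
    tau_E: float = 8.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if min(self.tau_R, self.tau_Vu, self.tau_E) <= 0:
            raise ValueError("baroreflex time constants must be > 0")
        if self.k_s <= 0:
            raise ValueError("sigmoid width k_s must be > 0")
        if self.P_set <= 0:
            raise ValueError("setpoint pressure must be > 0")


STATE_NAMES = (
    "V_lv", "V_rv",
    "P_sa", "Q_sa", "P_sp", "P_sv",
    "P_pa", "Q_pa", "P_pp", "P_pv",
    "Q_vad",
    "x_rsp", "x_vu", "x_emax",
)
N_STATES = len(STATE_NAMES)


@dataclass
class CirculationState:
    """Full model state at one instant (13 network states + pump flow)."""

    V_lv: float
    V_rv: float
    P_sa: float
    Q_sa: float
    P_sp: float
    P_sv: float
    P_pa: float
    Q_pa: float
    P_pp: float
    P_pv: float
    Q_vad: float = 0.0
    x_rsp: float = 1.0
    x_vu: float = 0.0
    x_emax: float = 1.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CirculationState":
        if len(y) != N_STATES:
            raise ValueError(f"state must have {N_STATES} components")
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})


class ReflexTargets(NamedTuple):
    r_scale: float
    vu_shift: float
    contractility: float


def valve_flow(P_up: float, P_down: float, R_open: float) -> float:
    """Ideal-diode valve: Ohmic forward flow, zero regurgitation (mL/s)."""
    if R_open <= 0:
        raise ValueError("R_open must be > 0")
    dP = P_up - P_down
    return dP / R_open if dP > 0 else 0.0


def _ramp(x: float, eps: float) -> float:
    """Smoothed positive part; exact max(x, 0) when eps == 0."""
    if eps <= 0:
        return x if x > 0 else 0.0
    return 0.5 * (x + math.sqrt(x * x + eps * eps))


def baroreflex_targets(MAP_filtered: float, bp: BaroreflexParams) -> ReflexTargets:
    """Effector targets for a sensed arterial pressure (negative feedback)."""
    if MAP_filtered <= 0:
        raise ValueError("sensed pressure must be > 0")
    s = 1.0 / (1.0 + math.exp((MAP_filtered - bp.P_set) / bp.k_s))
    g_R = bp.g_R_hypo if s > 0.5 else bp.g_R_hyper
    return ReflexTargets(
        r_scale=1.0 + g_R * (2.0 * s - 1.0),
        vu_shift=bp.Vu_span * (0.5 - s),
        contractility=1.0 + bp.g_E * (2.0 * s - 1.0),
    )


def total_blood_volume(state: CirculationState, vp: VascularParams) -> float:
    """Blood volume implied by the state: chambers + stressed + unstressed."""
    stressed = (
        vp.C_sa * state.P_sa + vp.C_sp * state.P_sp + vp.C_sv * state.P_sv
        + vp.C_pa * state.P_pa + vp.C_pp * state.P_pp + vp.C_pv * state.P_pv
    )
    return state.V_lv + state.V_rv + stressed + vp.unstressed_volume + state.x_vu


def derivatives(
    state: CirculationState,
    t: float,
    sc: "ScenarioConfig",
    omega: float,
    pump_connected: bool = True,
    diode_eps: float = 0.0,
    return_aux: bool = False,
):
    """Time derivative of the full state vector.

    ``omega`` is pump speed in rad/s; with ``pump_connected`` False the pump
    branch is absent (baseline, no-VAD configuration).  ``diode_eps`` > 0
    regularizes the valve diodes over that pressure width for smoothness.

    Raises an integration error naming the offending component if the state
    contains non-finite values.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        bad = [n for n, v in zip(STATE_NAMES, y) if not math.isfinite(v)]
        raise FloatingPointError(f"non-finite state component(s): {bad}")

    vp, bp, pp = sc.vascular, sc.baroreflex, sc.pump
    T = vp.period
    t_cyc = t - T * math.floor(t / T)
    e = activation(t_cyc, T, sc.lv.Ts_frac)

    # contractility scaling by the baroreflex effector
    lv = replace(sc.lv, lambda_asc=sc.lv.lambda_asc * state.x_emax, P_int=None)
    rv = replace(sc.rv, lambda_asc=sc.rv.lambda_asc * state.x_emax, P_int=None)

    # septal displacement and free-wall volumes (elastance pressures)
    V_spt = solve_septal_volume(state.V_lv, state.V_rv, e, lv, rv, sc.septum)
    V_lf, V_rf = partition_volumes(state.V_lv, state.V_rv, V_spt)

    # left ventricle: superposition pressure, viscous loss, aortic valve
    P_lv_sup = e * systolic_envelope(V_lf, lv) + (1.0 - e) * edp_envelope(V_lf, lv)
    Rv_lv = viscous_resistance(e, V_lf, lv)
    Q_vad = state.Q_vad if pump_connected else 0.0
    drive_ao = P_lv_sup - Rv_lv * Q_vad - state.P_sa
    Q_aov = _ramp(drive_ao, diode_eps) / (vp.R_aortic + Rv_lv)
    P_lv = P_lv_sup - Rv_lv * (Q_aov + Q_vad)
    Q_mi = _ramp(state.P_pv - P_lv, diode_eps) / vp.R_mitral

    # right ventricle: pulmonic and tricuspid valves
    P_rv_sup = e * systolic_envelope(V_rf, rv) + (1.0 - e) * edp_envelope(V_rf, rv)
    Rv_rv = viscous_resistance(e, V_rf, rv)
    Q_pov = _ramp(P_rv_sup - state.P_pa, diode_eps) / (vp.R_pulmonic + Rv_rv)
    P_rv = P_rv_sup - Rv_rv * Q_pov
    Q_ti = _ramp(state.P_sv - P_rv, diode_eps) / vp.R_tricuspid

    # pump branch
    if pump_connected:
        dQ_vad = pump_flow_derivative(P_lv, state.P_sa, state.Q_vad, omega, pp)
        R_suc = suction_resistance(P_lv, pp)
    else:
        dQ_vad = 0.0
        R_suc = 0.0

    # baroreflex effectors (first-order relaxation to sigmoid targets)
    if bp.enabled:
        tg = baroreflex_targets(state.P_sa, bp)
        dx_rsp = (tg.r_scale - state.x_rsp) / bp.tau_R
        dx_vu = (tg.vu_shift - state.x_vu) / bp.tau_Vu
        dx_emax = (tg.contractility - state.x_emax) / bp.tau_E
    else:
        dx_rsp = dx_vu = dx_emax = 0.0

    # vascular network (Kirchhoff current balances)
    R_sp_eff = vp.R_sp * state.x_rsp
    Q_sp = (state.P_sp - state.P_sv) / R_sp_eff
    Q_pp = (state.P_pp - state.P_pv) / vp.R_pp

    dV_lv = Q_mi - Q_aov - Q_vad
    dV_rv = Q_ti - Q_pov
    dP_sa = (Q_aov + Q_vad - state.Q_sa) / vp.C_sa
    dQ_sa = (state.P_sa - state.P_sp - vp.R_sa * state.Q_sa) / vp.L_sa
    dP_sp = (state.Q_sa - Q_sp) / vp.C_sp
    dP_sv = (Q_sp - Q_ti - dx_vu) / vp.C_sv
    dP_pa = (Q_pov - state.Q_pa) / vp.C_pa
    dQ_pa = (state.P_pa - state.P_pp - vp.R_pa * state.Q_pa) / vp.L_pa
    dP_pp = (state.Q_pa - Q_pp) / vp.C_pp
    dP_pv = (Q_pp - Q_mi) / vp.C_pv

    dy = np.array([
        dV_lv, dV_rv, dP_sa, dQ_sa, dP_sp, dP_sv,
        dP_pa, dQ_pa, dP_pp, dP_pv, dQ_vad, dx_rsp, dx_vu, dx_emax,
    ])
    if not return_aux:
        return dy
    aux = {
        "e": e, "V_spt": V_spt, "P_lv": P_lv, "P_rv": P_rv,
        "Q_aov": Q_aov, "Q_mi": Q_mi, "Q_pov": Q_pov, "Q_ti": Q_ti,
        "Q_sp": Q_sp, "Q_pp": Q_pp, "R_suc": R_suc,
        "Rv_lv": Rv_lv, "Rv_rv": Rv_rv,
    }
    return dy, aux
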
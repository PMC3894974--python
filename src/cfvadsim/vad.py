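"""Rotodynamic continuous-flow LVAD with cannulae and suction protection.

The pump is cannulated from the LV apex to the ascending aorta.  Its
quasi-steady characteristic is affine in flow with a speed-squared shutoff
head; an inertance term captures flow acceleration:

    H(Q, dQ/dt, omega) = beta2*omega^2 - beta0*Q - beta1*dQ/dt   [mmHg]

with omega in rad/s and Q in mL/s.  H is the outlet-minus-inlet pressure
rise, so the pump sustains positive flow against an adverse aortic-to-LV
gradient whenever the speed head exceeds it.  Coefficients default to a
clinically used axial pump (shutoff head ~80 mmHg at 9000 RPM).

A nonlinear suction resistor between LV and inflow cannula engages when LV
pressure falls below a threshold, ramping up linearly to throttle pump inflow
and so bound ventricular collapse (suck-down).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


RPM_TO_RAD = 2.0 * math.pi / 60.0


@dataclass
class PumpParams:
    """cfVAD characteristic and cannula parameters.

    beta0 (mmHg*s/mL), beta1 (mmHg*s^2/mL) and beta2 (mmHg*s^2/rad^2) are
    stored as positive magnitudes under the outlet-minus-inlet convention.
    """

    beta0: float = 0.1707
    beta1: float = 0.02177
    beta2: float = 0.0000903
    R_in: float = 0.0677
    R_out: float = 0.0677
    L_in: float = 0.0127
    L_out: float = 0.0127
    P_th: float = 1.0
    k_suc: float = 3.5

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2", "R_in", "R_out", "L_in", "L_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_suc < 0:
            raise ValueError("k_suc must be >= 0")
        if not math.isfinite(self.P_th):
            raise ValueError("P_th must be finite")
        if self.total_inertance <= 0:
            raise ValueError("total inertance (L_in + L_out + beta1) must be > 0")

    @property
    def total_inertance(self) -> float:
        return self.L_in + self.L_out + self.beta1


def rpm_to_rad(rpm: float) -> float:
    """Convert pump speed from RPM to rad/s."""
    return rpm * RPM_TO_RAD


def pump_head(Q: float, dQdt: float, omega: float, p: PumpParams) -> float:
    """Pressure rise across the pump (outlet minus inlet, mmHg)."""
    if omega < 0:
        raise ValueError("omega must be >= 0")
    return p.beta2 * omega * omega - p.beta0 * Q - p.beta1 * dQdt


def suction_resistance(P_lv: float, p: PumpParams) -> float:
    """Inlet suction resistance (mmHg*s/mL), zero above the threshold.

    Ramps linearly as LV pressure falls below P_th; continuous at the
    threshold.
    """
    if P_lv > p.P_th:
        return 0.0
    return p.k_suc * (p.P_th - P_lv)


def pump_flow_derivative(
    P_lv: float, P_ao: float, Q: float, omega: float, p: PumpParams
) -> float:
    """Rate of change of pump flow (mL/s^2) over the full apex-aorta branch.

    Momentum balance across inflow cannula, pump and outflow cannula;
    negative Q (regurgitant pump flow at low speed against a high gradient)
    is permitted.
    """
    R_total = p.R_in + p.R_out + suction_resistance(P_lv, p) + p.beta0
    head = p.beta2 * omega * omega
    return ((P_lv - P_ao) + head - R_total * Q) / p.total_inertance
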
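"""Constitutive model of a single ventricle.

Instantaneous ventricular pressure is a time-varying-elastance superposition
of an end-systolic envelope (ESPVR) and an end-diastolic envelope (EDPVR),

    P(t, V) = e(t) * P_es(V) + (1 - e(t)) * P_ed(V) - R_v * Q_eject,

where ``e(t)`` is a normalized activation waveform and the last term is the
viscous pressure loss of ejection (Shroff-type intraventricular resistance).

The ESPVR is deliberately *unimodal*: a bilinear curve with a physiological
ascending limb and a pathological descending limb beyond a transition volume.
A dilated, overloaded ventricle operating past the transition exhibits the
descending limb of the Starling response — increasing preload *reduces*
developed pressure and stroke work, which a conventional monotone (linear)
ESPVR cannot represent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class VentricleParams:
    """Constitutive constants of one ventricle.

    Parameters
    ----------
    lambda_asc : float
        Slope of the ascending ESPVR limb (mmHg/mL); the classical Emax.
    lambda_desc : float
        Slope of the pathological descending limb (mmHg/mL, negative).
    V_transition : float
        Volume at the bilinear cusp (mL) — the limit of preload reserve.
    V0 : float
        Unstressed volume (mL) at which both envelopes give zero pressure.
    A_ed, B_ed : float
        EDPVR exponential coefficients: P_ed = A_ed * (exp(B_ed*(V-V0)) - 1).
    Rv_coeff : float
        Intraventricular resistance coefficient. By default the resistance
        scales with the instantaneous isovolumic (developed) pressure,
        R_v = Rv_coeff * e(t) * P_es(V) / (1 mmHg); with ``rv_constant`` set,
        R_v = Rv_coeff (mmHg*s/mL) directly.
    Ts_frac : float
        Systolic fraction of the cardiac period, in (0, 1).
    P_int : float, optional
        Pressure-axis intercept of the descending limb (mmHg); redundant with
        the other ESPVR parameters and checked for consistency when given.
    """

    lambda_asc: float
    lambda_desc: float
    V_transition: float
    V0: float
    A_ed: float
    B_ed: float
    Rv_coeff: float = 0.0
    Ts_frac: float = 0.3
    P_int: float | None = field(default=None)
    rv_constant: bool = False

    def __post_init__(self) -> None:
        if self.lambda_asc <= 0:
            raise ValueError("lambda_asc must be > 0")
        if self.lambda_desc >= 0:
            raise ValueError("lambda_desc must be < 0")
        if self.V_transition <= self.V0:
            raise ValueError("V_transition must exceed V0")
        if self.A_ed < 0 or self.B_ed <= 0:
            raise ValueError("EDPVR requires A_ed >= 0 and B_ed > 0")
        if not 0.0 < self.Ts_frac < 1.0:
            raise ValueError("Ts_frac must lie in (0, 1)")
        if self.Rv_coeff < 0:
            raise ValueError("Rv_coeff must be >= 0")
        if self.P_int is not None:
            expected = self.pressure_intercept()
            if abs(self.P_int - expected) > 1e-6 * max(1.0, abs(expected)):
                raise ValueError(
                    f"P_int={self.P_int} inconsistent with ESPVR geometry "
                    f"(expected {expected:.6g})"
                )

    @property
    def peak_es_pressure(self) -> float:
        """ESPVR pressure at the transition volume (top of the envelope)."""
        return self.lambda_asc * (self.V_transition - self.V0)

    def pressure_intercept(self) -> float:
        """Pressure-axis intercept of the (extrapolated) descending limb."""
        return self.peak_es_pressure - self.lambda_desc * self.V_transition


def activation(t_in_cycle: float, T: float, Ts_frac: float) -> float:
    """Normalized activation waveform e(t) in [0, 1].

    Squared half-sine over systole: e = sin^2(pi*t/(Ts_frac*T)) for
    t < Ts_frac*T, zero through diastole. Starts at zero, peaks at 1 at
    mid-systole, and is continuous at the systole/diastole junction.
    """
    if T <= 0:
        raise ValueError("cardiac period T must be positive")
    if not 0.0 < Ts_frac < 1.0:
        raise ValueError("Ts_frac must lie in (0, 1)")
    if not 0.0 <= t_in_cycle < T:
        raise ValueError("t_in_cycle must satisfy 0 <= t < T")
    t_sys = Ts_frac * T
    if t_in_cycle >= t_sys:
        return 0.0
    s = math.sin(math.pi * t_in_cycle / t_sys)
    return s * s


def esp_envelope(V: float, p: VentricleParams) -> float:
    """Unimodal (bilinear) end-systolic pressure at volume ``V`` (mmHg).

    Ascending limb lambda_asc*(V - V0) up to the transition volume, then a
    descending limb through the cusp with slope lambda_desc; clipped at zero
    because contraction alone cannot produce negative pressure.
    """
    if V <= p.V_transition:
        P = p.lambda_asc * (V - p.V0)
    else:
        P = p.peak_es_pressure + p.lambda_desc * (V - p.V_transition)
    return max(P, 0.0)


def esp_slope(V: float, p: VentricleParams) -> float:
    """d(P_es)/dV of the active ESPVR branch (0 where clipped)."""
    if V <= p.V_transition:
        return p.lambda_asc if V >= p.V0 else 0.0
    P = p.peak_es_pressure + p.lambda_desc * (V - p.V_transition)
    return p.lambda_desc if P > 0.0 else 0.0


def edp_envelope(V: float, p: VentricleParams) -> float:
    """Exponential end-diastolic (passive filling) pressure (mmHg).

    Zero at the unstressed volume, strictly increasing and convex above it,
    clipped at zero below it.
    """
    if V <= p.V0:
        return 0.0
    return p.A_ed * math.expm1(p.B_ed * (V - p.V0))


def edp_slope(V: float, p: VentricleParams) -> float:
    """d(P_ed)/dV (0 below the unstressed volume)."""
    if V <= p.V0:
        return 0.0
    return p.A_ed * p.B_ed * math.exp(p.B_ed * (V - p.V0))


def systolic_envelope(V: float, p: VentricleParams) -> float:
    """End-systolic envelope floored at the passive (EDPVR) curve (mmHg).

    The contracting muscle always carries at least its passive tension, so
    the operative end-systolic envelope can never lie below the EDPVR: at
    extreme dilation (where the clipped descending limb would dip under the
    exponential filling curve) activation holds pressure at the passive
    value rather than below it.  Within the physiologic operating range the
    floor is inactive and this equals the raw bilinear ESPVR.
    """
    return max(esp_envelope(V, p), edp_envelope(V, p))


def systolic_envelope_slope(V: float, p: VentricleParams) -> float:
    """dP/dV of the floored systolic envelope (for implicit solves)."""
    if esp_envelope(V, p) >= edp_envelope(V, p):
        return esp_slope(V, p)
    return edp_slope(V, p)


def viscous_resistance(e: float, V: float, p: VentricleParams) -> float:
    """Instantaneous intraventricular ejection resistance (mmHg*s/mL)."""
    if p.rv_constant:
        return p.Rv_coeff
    return p.Rv_coeff * e * systolic_envelope(V, p)  # P_ref = 1 mmHg


def ventricular_pressure(
    t_in_cycle: float,
    V: float,
    Q_eject: float,
    p: VentricleParams,
    T: float,
) -> float:
    """Instantaneous chamber pressure (mmHg).

    ``Q_eject`` is the total outward ejection flow (for an assisted LV, valve
    flow plus the flow drawn by the pump inlet).
    """
    e = activation(t_in_cycle, T, p.Ts_frac)
    P_es = systolic_envelope(V, p)
    P_ed = edp_envelope(V, p)
    Rv = viscous_resistance(e, V, p)
    return e * P_es + (1.0 - e) * P_ed - Rv * Q_eject
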
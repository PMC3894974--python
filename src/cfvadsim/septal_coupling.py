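"""Ventricular interdependence through a time-varying septal elastance.

The interventricular septum is a shared elastic wall: a transseptal pressure
difference displaces a volume V_spt from the neutral septal position toward
the RV (positive sign).  Each chamber's constitutive law then acts on its
*free-wall* (neutral) volume rather than its total cavity volume:

    V_lv_free = V_lv_total - V_spt,     V_rv_free = V_rv_total + V_spt,
    V_spt     = (P_lv - P_rv) / E_spt(e),
    E_spt(e)  = e * Es_sys + (1 - e) * Es_dia.

The septum stiffens with systole through the same activation waveform as the
LV.  Because P_lv and P_rv themselves depend on the partitioned volumes, the
instantaneous septal displacement is the root of a scalar fixed-point
equation, solved here by a safeguarded Newton iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

from .heart_chambers import (
    VentricleParams,
    edp_envelope,
    edp_slope,
    systolic_envelope,
    systolic_envelope_slope,
)


@dataclass
class SeptumParams:
    """Septal elastances (mmHg/mL): end-systolic and end-diastolic."""

    Es_sys: float
    Es_dia: float

    def __post_init__(self) -> None:
        if not self.Es_sys >= self.Es_dia > 0:
            raise ValueError("require Es_sys >= Es_dia > 0")


def septal_elastance(e: float, sp: SeptumParams) -> float:
    """Instantaneous septal elastance, activation-weighted (mmHg/mL)."""
    E = e * sp.Es_sys + (1.0 - e) * sp.Es_dia
    if E <= 0:
        raise ValueError("septal elastance must be positive")
    return E


def septal_displaced_volume(
    P_lv: float, P_rv: float, e: float, sp: SeptumParams
) -> float:
    """Volume displaced toward the RV by the transseptal pressure (mL).

    Positive when the LV pressurizes the septum rightward; negative values
    are the leftward septal shift seen with LV over-decompression.
    """
    if not 0.0 <= e <= 1.0:
        raise ValueError("activation e must lie in [0, 1]")
    return (P_lv - P_rv) / septal_elastance(e, sp)


def partition_volumes(
    V_lv_total: float, V_rv_total: float, V_spt: float
) -> tuple[float, float]:
    """Split total cavity volumes into free-wall (neutral) volumes.

    Conserves total biventricular volume for any displacement.
    """
    return V_lv_total - V_spt, V_rv_total + V_spt


def _elastance_pressure(V: float, e: float, p: VentricleParams) -> float:
    return e * systolic_envelope(V, p) + (1.0 - e) * edp_envelope(V, p)


def _elastance_stiffness(V: float, e: float, p: VentricleParams) -> float:
    return (e * systolic_envelope_slope(V, p)
            + (1.0 - e) * edp_slope(V, p))


def solve_septal_volume(
    V_lv_total: float,
    V_rv_total: float,
    e: float,
    lv: VentricleParams,
    rv: VentricleParams,
    sp: SeptumParams,
    tol: float = 1e-10,
    max_iter: int = 50,
) -> float:
    """Self-consistent septal displacement for given total cavity volumes.

    Solves g(V_spt) = E_spt*V_spt - (P_lv - P_rv) = 0 where the chamber
    pressures are the elastance superpositions evaluated at the partitioned
    free-wall volumes.  g is monotone increasing (the septal plus chamber
    stiffnesses dominate the bilinear descending limb for physiologic
    parameters), so Newton with a bisection safeguard converges in a few
    iterations to a residual below ``tol`` mmHg.
    """
    E = septal_elastance(e, sp)
    x = 0.0
    lo, hi = -0.6 * V_rv_total, 0.6 * V_lv_total
    for _ in range(max_iter):
        V_lf, V_rf = partition_volumes(V_lv_total, V_rv_total, x)
        dP = _elastance_pressure(V_lf, e, lv) - _elastance_pressure(V_rf, e, rv)
        g = E * x - dP
        if abs(g) < tol:
            return x
        if g > 0:
            hi = min(hi, x)
        else:
            lo = max(lo, x)
        dg = E + _elastance_stiffness(V_lf, e, lv) + _elastance_stiffness(V_rf, e, rv)
        step = g / dg if dg > 0 else 0.0
        x_new = x - step
        if not lo <= x_new <= hi or dg <= 0:
            x_new = 0.5 * (lo + hi)
        x = x_new
    return x
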
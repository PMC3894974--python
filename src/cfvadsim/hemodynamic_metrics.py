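"""Per-beat hemodynamic indices derived from converged trajectories.

Stroke work is the area of the ventricular pressure-volume loop, reported in
gram-meters per beat: 1 mmHg*mL = 1.33322e-4 J and 1 gm-m = 9.80665e-3 J,
hence the conversion factor 0.0135951 gm-m per mmHg*mL.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

GRAM_METER_PER_MMHG_ML = 1.33322e-4 / 9.80665e-3  # = 0.0135951...
DEFAULT_BSA = 1.9  # m^2, assumed adult body surface area


@dataclass
class BeatMetrics:
    """Derived indices for one converged beat (flows in L/min unless noted)."""

    HR: float
    CO_total: float
    Q_aov_mean: float
    Q_vad_mean: float
    SV: float            # mL, LV max-min volume excursion
    EF: float            # %, LV
    SW: float            # gm-m/beat
    SWI: float           # gm-m/beat/m^2
    EDP: float           # mmHg, LV
    EDV: float           # mL, LV
    ESV: float           # mL, LV
    LAP: float
    RAP: float
    MAP: float
    SBP: float
    DBP: float
    PAs: float
    PAd: float
    PAm: float
    PCWP: float
    TPG: float
    PVR: float           # Wood units
    ES_AP: float         # arterial pressure at end systole, mmHg
    V_lv_es: float       # LV volume at end systole (activation peak), mL
    RV_EDP: float
    RV_EDV: float
    RV_ESV: float
    RV_EF: float
    min_P_lv: float

    def as_dict(self) -> dict:
        return asdict(self)


def stroke_work(pv_loop: Sequence[tuple[float, float]]) -> float:
    """Stroke work (gm-m) of one closed PV loop via the shoelace formula.

    ``pv_loop`` is an ordered sequence of (volume mL, pressure mmHg) samples
    tracing one cardiac cycle; endpoints must close within 1 mL / 1 mmHg.
    """
    loop = np.asarray(pv_loop, dtype=float)
    if loop.ndim != 2 or loop.shape[1] != 2 or len(loop) < 3:
        raise ValueError("pv_loop must be a sequence of (V, P) pairs")
    V, P = loop[:, 0], loop[:, 1]
    if abs(V[0] - V[-1]) > 1.0 or abs(P[0] - P[-1]) > 1.0:
        raise ValueError("PV loop is not closed (endpoints differ by > 1 mL/mmHg)")
    area = 0.5 * abs(np.sum(V * np.roll(P, -1) - np.roll(V, -1) * P))
    return area * GRAM_METER_PER_MMHG_ML


def stroke_work_index(SW: float, BSA: float = DEFAULT_BSA) -> float:
    """Stroke work normalized by body surface area (gm-m/beat/m^2)."""
    if BSA <= 0:
        raise ValueError("BSA must be > 0")
    return SW / BSA


def effective_arterial_elastance(
    points: Sequence[tuple[float, float]]
) -> float:
    """Least-squares slope of end-systolic pressure vs stroke volume (mmHg/mL).

    ``points`` holds (ES pressure, SV) pairs across loading conditions; at
    least two distinct stroke volumes are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (ES pressure, SV) points")
    P, SV = pts[:, 0], pts[:, 1]
    if np.ptp(SV) == 0:
        raise ValueError("stroke volumes are not distinct")
    slope = np.polyfit(SV, P, 1)[0]
    return float(slope)


def extremal_loading(sweep: Iterable[tuple[float, float]]) -> float:
    """Pump speed (RPM) at which LV stroke work is maximal.

    ``sweep`` is an iterable of (rpm, SW) rows (a DataFrame with 'rpm' and
    'SW' columns also works).  Ties break toward the lower speed — the least
    support consistent with maximal intrinsic work.
    """
    if hasattr(sweep, "columns"):
        rows = list(zip(sweep["rpm"], sweep["SW"]))
    else:
        rows = list(sweep)
    if not rows:
        raise ValueError("sweep table is empty")
    rows.sort(key=lambda r: r[0])
    best_rpm, best_sw = rows[0]
    for rpm, sw in rows[1:]:
        if sw > best_sw:
            best_rpm, best_sw = rpm, sw
    return best_rpm


def ap_vs_esv_locus(results) -> list[tuple[float, float]]:
    """(end-systolic arterial pressure, end-systolic LV volume) per speed.

    ``results`` is an iterable of BeatMetrics (or a sweep DataFrame with
    'ES_AP' and 'V_lv_es' columns), one entry per pump speed; used for
    recovery-assessment loci.
    """
    if hasattr(results, "columns"):
        return list(zip(results["ES_AP"], results["V_lv_es"]))
    return [(m.ES_AP, m.V_lv_es) for m in results]


def preload_adjusted_maximal_power(*args, **kwargs):
    """Stub: preload-adjusted maximal power.

    The definition used for this index varies across the literature and no
    validated reference values are available for this model; deliberately
    unimplemented.
    """
    raise NotImplementedError(
        "preload-adjusted maximal power is not validated for this model"
    )


def beat_metrics(
    t: np.ndarray,
    Y: np.ndarray,
    AUX: np.ndarray,
    heart_rate: float,
    Ts_frac: float,
    pump_connected: bool,
    BSA: float = DEFAULT_BSA,
) -> BeatMetrics:
    """Compute BeatMetrics from sampled state/aux arrays spanning one beat.

    ``Y`` and ``AUX`` follow the state and aux layouts of the compiled core;
    the samples must cover exactly one cardiac period including both
    endpoints.
    """
    from ._core import AUX_NAMES

    T = 60.0 / heart_rate
    aux = {name: AUX[:, i] for i, name in enumerate(AUX_NAMES)}
    V_lv = Y[:, 0]
    V_rv = Y[:, 1]
    P_sa = Y[:, 2]
    P_sv = Y[:, 5]
    P_pa = Y[:, 6]
    P_pv = Y[:, 9]
    Q_vad = Y[:, 10] if pump_connected else np.zeros_like(t)
    P_lv = aux["P_lv"]
    P_rv = aux["P_rv"]
    Q_aov = aux["Q_aov"]

    span = t[-1] - t[0]
    if abs(span - T) > 0.02 * T:
        raise ValueError("samples must span exactly one cardiac period")

    def tmean(x):
        return float(np.trapezoid(x, t) / span)

    q_aov_lmin = tmean(Q_aov) * 0.06
    q_vad_lmin = tmean(Q_vad) * 0.06
    co_total = q_aov_lmin + q_vad_lmin

    edv, esv = float(np.max(V_lv)), float(np.min(V_lv))
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else 0.0
    # end-diastolic pressures are read at beat start (pre-contraction),
    # before early activation contaminates the passive filling pressure
    edp = float(P_lv[0])

    rv_edv, rv_esv = float(np.max(V_rv)), float(np.min(V_rv))
    rv_ef = 100.0 * (rv_edv - rv_esv) / rv_edv if rv_edv > 0 else 0.0
    rv_edp = float(P_rv[0])

    # shoelace area without the closure check (transient beats need not close)
    Vc, Pc = V_lv[:-1], P_lv[:-1]
    area = 0.5 * abs(np.sum(Vc * np.roll(Pc, -1) - np.roll(Vc, -1) * Pc))
    sw = area * GRAM_METER_PER_MMHG_ML
    lap = tmean(P_pv)
    pam = tmean(P_pa)
    pcwp = lap
    tpg = pam - pcwp
    pvr = tpg / co_total if co_total > 1e-9 else float("nan")

    # end systole = peak of the activation waveform, at Ts_frac*T/2 into the cycle
    t_cyc = np.mod(t - t[0] + np.mod(t[0], T), T)
    i_es = int(np.argmin(np.abs(t_cyc - 0.5 * Ts_frac * T)))

    return BeatMetrics(
        HR=heart_rate,
        CO_total=co_total,
        Q_aov_mean=q_aov_lmin,
        Q_vad_mean=q_vad_lmin,
        SV=sv,
        EF=ef,
        SW=sw,
        SWI=stroke_work_index(sw, BSA),
        EDP=edp,
        EDV=edv,
        ESV=esv,
        LAP=lap,
        RAP=tmean(P_sv),
        MAP=tmean(P_sa),
        SBP=float(np.max(P_sa)),
        DBP=float(np.min(P_sa)),
        PAs=float(np.max(P_pa)),
        PAd=float(np.min(P_pa)),
        PAm=pam,
        PCWP=pcwp,
        TPG=tpg,
        PVR=pvr,
        ES_AP=float(P_sa[i_es]),
        V_lv_es=float(V_lv[i_es]),
        RV_EDP=rv_edp,
        RV_EDV=rv_edv,
        RV_ESV=rv_esv,
        RV_EF=rv_ef,
        min_P_lv=float(np.min(P_lv)),
    )
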
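"""Scenario management, integration to periodic steady state, speed sweeps.

A ScenarioConfig bundles every parameter set of one simulated condition
(normal baseline or one of four dilated-failure conditions).  The engine
integrates the closed-loop model beat by beat with a fixed, beat-aligned RK4
step until per-beat metrics (CO, MAP, EDV) and the beat-start state are
periodic, then reports metrics from a window of converged beats.

The speed-sweep protocol raises pump speed stepwise (6k-12k RPM by default),
warm-starting each speed from the previous converged state, and tabulates the
full hemodynamic index set per speed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from . import _core
from .circulatory_network import (
    BaroreflexParams,
    CirculationState,
    VascularParams,
)
from .heart_chambers import VentricleParams
from .hemodynamic_metrics import BeatMetrics, beat_metrics
from .septal_coupling import SeptumParams
from .vad import PumpParams, rpm_to_rad

logger = logging.getLogger("cfvadsim.engine")

SCENARIO_NAMES = ("normal", "lvf", "bif", "lvf_pvr", "bif_pvr")
_ALIASES = {
    "normal": "normal",
    "lvf": "lvf",
    "bi-f": "bif",
    "bif": "bif",
    "lvf_pvr": "lvf_pvr",
    "lvf+pvr+": "lvf_pvr",
    "bif_pvr": "bif_pvr",
    "bi-f+pvr+": "bif_pvr",
}


@dataclass
class IntegrationSettings:
    """Fixed-step integrator configuration.

    dt is a target step (s); the actual step is snapped so a cardiac period
    is an integer number of steps.  diode_eps regularizes the valve diodes.
    """

    dt: float = 1e-4
    sample_dt: float = 1e-3
    max_beats: int = 200
    min_beats: int = 10
    conv_tol: float = 0.005
    n_report_beats: int = 5
    diode_eps: float = 0.01

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.sample_dt < self.dt:
            raise ValueError("require 0 < dt <= sample_dt")
        if not 0 < self.conv_tol < 1:
            raise ValueError("conv_tol must be in (0, 1)")


@dataclass
class ScenarioConfig:
    """One named condition bundling all model parameters."""

    name: str
    lv: VentricleParams
    rv: VentricleParams
    septum: SeptumParams
    vascular: VascularParams
    baroreflex: BaroreflexParams
    pump: PumpParams
    BSA: float = 1.9
    pump_speed_schedule: list[tuple[float, float]] | None = None
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["lv"] = VentricleParams(**d["lv"])
        d["rv"] = VentricleParams(**d["rv"])
        d["septum"] = SeptumParams(**d["septum"])
        d["vascular"] = VascularParams(**d["vascular"])
        d["baroreflex"] = BaroreflexParams(**d["baroreflex"])
        d["pump"] = PumpParams(**d["pump"])
        d["integration"] = IntegrationSettings(**d.get("integration", {}))
        if d.get("pump_speed_schedule") is not None:
            d["pump_speed_schedule"] = [tuple(p) for p in d["pump_speed_schedule"]]
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def load_scenario(name: str) -> ScenarioConfig:
    """Load one of the shipped scenario fixtures by (alias-tolerant) name."""
    key = _ALIASES.get(name.lower().replace(" ", ""))
    if key is None:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    ref = resources.files("cfvadsim").joinpath(f"scenarios/{key}.json")
    with ref.open() as fh:
        return ScenarioConfig.from_dict(json.load(fh))


@dataclass
class SimulationResult:
    """Outcome of one steady-state run."""

    scenario: str
    omega_rpm: float | None
    t: np.ndarray
    Y: np.ndarray
    AUX: np.ndarray
    beats: list[BeatMetrics]
    metrics: BeatMetrics
    converged: bool
    n_beats: int
    final_state: CirculationState
    dt: float


def initial_state(sc: ScenarioConfig) -> CirculationState:
    """Start state in diastolic passive equilibrium with the volume budget.

    Arterial-side pressures are seeded at rough normal values; the
    remaining blood volume is placed in the two venous reservoirs at a
    common filling pressure, with each ventricle on its passive (EDPVR)
    curve at that pressure.  This makes the start state reflect the
    configured total blood volume: volume-overloaded (decompensated)
    conditions begin congested and relax within their own basin of
    attraction rather than being launched from a healthy-volume state —
    the unimodal ESPVR admits distinct compensated and congested periodic
    states at the same parameters, and disease history selects the latter.
    """
    vp = sc.vascular
    if vp.total_blood_volume <= 0:
        return CirculationState(0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    P_sa, P_sp, P_pa, P_pp = 90.0, 85.0, 22.0, 16.0
    stressed_other = (
        vp.C_sa * P_sa + vp.C_sp * P_sp + vp.C_pa * P_pa + vp.C_pp * P_pp
    )
    budget = vp.total_blood_volume - vp.unstressed_volume - stressed_other
    C_ven = vp.C_sv + vp.C_pv

    def passive_volume(P: float, p) -> float:
        if P <= 0:
            return max(p.V0 * 0.5, 1.0)
        return p.V0 + math.log(P / p.A_ed + 1.0) / p.B_ed

    P_fill = max(budget / (C_ven + 40.0), 1.0)  # rough first guess
    for _ in range(60):
        V_lv = passive_volume(P_fill, sc.lv)
        V_rv = passive_volume(P_fill, sc.rv)
        P_new = (budget - V_lv - V_rv) / C_ven
        if P_new <= 0:
            raise ValueError(
                "total blood volume too small for the configured compliances"
            )
        if abs(P_new - P_fill) < 1e-10:
            P_fill = P_new
            break
        P_fill = 0.5 * (P_fill + P_new)
    V_lv = passive_volume(P_fill, sc.lv)
    V_rv = passive_volume(P_fill, sc.rv)
    return CirculationState(
        V_lv=V_lv, V_rv=V_rv, P_sa=P_sa, Q_sa=80.0, P_sp=P_sp, P_sv=P_fill,
        P_pa=P_pa, Q_pa=80.0, P_pp=P_pp, P_pv=P_fill,
    )


def _beat_grid(sc: ScenarioConfig) -> tuple[int, float, int]:
    """Steps per beat, actual dt and sample stride for this scenario."""
    cfg = sc.integration
    T = sc.vascular.period
    ratio = max(1, round(cfg.sample_dt / cfg.dt))
    n_coarse = max(2, round(T / (ratio * cfg.dt)))
    n_steps = n_coarse * ratio
    dt = T / n_steps
    return n_steps, dt, ratio


def run_to_steady_state(
    sc: ScenarioConfig,
    omega_rpm: float | None = None,
    y0: CirculationState | None = None,
    max_beats: int | None = None,
) -> SimulationResult:
    """Integrate to periodic steady state and extract converged-beat metrics.

    ``omega_rpm`` is the constant pump speed; None disconnects the pump
    entirely (baseline, no-VAD configuration).  Non-convergence within the
    beat cap yields a flagged result, not an exception; a non-finite state
    raises ``FloatingPointError``.
    """
    cfg = sc.integration
    connected = omega_rpm is not None
    omega = rpm_to_rad(omega_rpm) if connected else 0.0
    pp = _core.pack_params(sc, omega, connected, cfg.diode_eps)
    n_steps, dt, stride = _beat_grid(sc)
    cap = cfg.max_beats if max_beats is None else max_beats

    y = (y0 or initial_state(sc)).as_array()
    if connected is False:
        y[10] = 0.0

    t0 = 0.0
    prev = None
    prev_y = y.copy()
    converged = False
    n_beats = 0
    for beat in range(cap):
        ts, Ys, AUXs, y = _core.rk4_integrate(y, pp, t0, n_steps, dt, stride)
        t0 += n_steps * dt
        n_beats += 1
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite state after beat {n_beats} "
                f"({sc.name}, rpm={omega_rpm})"
            )
        m = beat_metrics(ts, Ys, AUXs, sc.vascular.heart_rate,
                         sc.lv.Ts_frac, connected, sc.BSA)
        if prev is not None and n_beats >= cfg.min_beats:
            rel = [
                abs(m.CO_total - prev.CO_total) / max(abs(prev.CO_total), 0.1),
                abs(m.MAP - prev.MAP) / max(abs(prev.MAP), 1.0),
                abs(m.EDV - prev.EDV) / max(abs(prev.EDV), 1.0),
            ]
            state_rel = np.max(
                np.abs(y - prev_y) / np.maximum(np.abs(prev_y), 1.0)
            )
            if max(rel) < cfg.conv_tol and state_rel < cfg.conv_tol:
                converged = True
                break
        prev = m
        prev_y = y.copy()

    # report window: n_report_beats further beats
    all_t, all_Y, all_AUX, beats = [], [], [], []
    for k in range(cfg.n_report_beats):
        ts, Ys, AUXs, y = _core.rk4_integrate(y, pp, t0, n_steps, dt, stride)
        t0 += n_steps * dt
        beats.append(beat_metrics(ts, Ys, AUXs, sc.vascular.heart_rate,
                                  sc.lv.Ts_frac, connected, sc.BSA))
        sl = slice(0, -1) if k < cfg.n_report_beats - 1 else slice(None)
        all_t.append(ts[sl])
        all_Y.append(Ys[sl])
        all_AUX.append(AUXs[sl])

    logger.info(
        "%s rpm=%s: %s after %d beats (CO=%.2f L/min, MAP=%.1f mmHg)",
        sc.name, omega_rpm,
        "converged" if converged else "NOT converged", n_beats,
        beats[-1].CO_total, beats[-1].MAP,
    )
    fields = [f.name for f in dataclasses.fields(BeatMetrics)]
    mean_metrics = BeatMetrics(**{
        f: float(np.mean([getattr(b, f) for b in beats])) for f in fields
    })
    return SimulationResult(
        scenario=sc.name,
        omega_rpm=omega_rpm,
        t=np.concatenate(all_t),
        Y=np.concatenate(all_Y),
        AUX=np.concatenate(all_AUX),
        beats=beats,
        metrics=mean_metrics,
        converged=converged,
        n_beats=n_beats,
        final_state=CirculationState.from_array(y),
        dt=dt,
    )


def speed_sweep(
    sc: ScenarioConfig,
    speeds: Sequence[float],
    baseline: SimulationResult | None = None,
) -> pd.DataFrame:
    """One converged run per pump speed, warm-started speed to speed.

    Returns a DataFrame with one row per speed carrying the full index set
    plus fractional EDV change and %SV change versus the no-VAD baseline.
    The per-speed SimulationResults are attached as ``df.attrs['results']``.
    """
    if len(speeds) == 0:
        raise ValueError("speeds must be nonempty")
    if baseline is None:
        baseline = run_to_steady_state(sc, None)
    rows = []
    results = []
    state = baseline.final_state
    for rpm in speeds:
        try:
            res = run_to_steady_state(sc, rpm, y0=state)
            state = res.final_state
            row = {"rpm": float(rpm), **res.metrics.as_dict(),
                   "converged": res.converged, "failed": False}
            row["dEDV_frac"] = (
                (res.metrics.EDV - baseline.metrics.EDV) / baseline.metrics.EDV
            )
            row["dSV_pct"] = 100.0 * (
                (res.metrics.SV - baseline.metrics.SV) / baseline.metrics.SV
            )
        except FloatingPointError:
            res = None
            row = {"rpm": float(rpm), "converged": False, "failed": True}
        rows.append(row)
        results.append(res)
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    df.attrs["baseline"] = baseline
    return df


def _get_by_path(sc: ScenarioConfig, path: str):
    obj = sc
    for part in path.split("."):
        obj = getattr(obj, part)
    return obj


def _set_by_path(sc: ScenarioConfig, path: str, value: float) -> None:
    parts = path.split(".")
    obj = sc
    for part in parts[:-1]:
        obj = getattr(obj, part)
    setattr(obj, parts[-1], value)


def calibrate_scalar(
    sc: ScenarioConfig,
    param_path: str,
    bounds: tuple[float, float],
    metric: str,
    target: float,
    omega_rpm: float | None = None,
    rtol: float = 0.01,
    max_iter: int = 24,
) -> float:
    """Bounded scalar search tuning one parameter to hit one metric.

    Bisects ``param_path`` (dotted attribute path, e.g. ``vascular.R_sp``)
    within physiologic ``bounds`` until the named converged-beat metric is
    within ``rtol`` of ``target``; returns the tuned value (left set on the
    config).  Assumes the metric responds monotonically over the bracket,
    which holds for the intended uses (resistance -> pressure,
    volume -> preload, contractility -> output).
    """

    def f(x: float) -> float:
        _set_by_path(sc, param_path, x)
        res = run_to_steady_state(sc, omega_rpm)
        return getattr(res.metrics, metric) - target

    lo, hi = bounds
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        # no sign change: keep the better endpoint
        x = lo if abs(flo) < abs(fhi) else hi
        _set_by_path(sc, param_path, x)
        return x
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) <= rtol * max(abs(target), 1e-9):
            return mid
        if flo * fm <= 0:
            hi, fhi = mid, fm
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
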
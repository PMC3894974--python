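"""Synthetic PV-loop generators and the benchmark regression harness.

The benchmark records encode the published baseline hemodynamics of the five
simulated conditions (normal plus four dilated-failure states) and the
reported speed-sweep extremals; ``run_benchmarks`` replays the shipped
scenario fixtures against them and emits a machine-readable report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulation_engine import (
    ScenarioConfig,
    SimulationResult,
    load_scenario,
    run_to_steady_state,
)


# --- synthetic PV loops ------------------------------------------------------

def make_synthetic_pv_loop(
    shape: str,
    *,
    dP: float = 100.0,
    dV: float = 50.0,
    P0: float = 10.0,
    V0: float = 60.0,
    a: float = 30.0,
    b: float = 40.0,
    center: tuple[float, float] = (120.0, 60.0),
    n: int = 200,
    result: SimulationResult | None = None,
) -> np.ndarray:
    """Closed, counterclockwise (V, P) loop with analytically known area.

    shapes: ``rectangle`` (area dP*dV), ``ellipse`` (semi-axes a=volume,
    b=pressure; area pi*a*b), or ``sampled`` (last converged beat of a
    SimulationResult).
    """
    if shape == "rectangle":
        if dP <= 0 or dV <= 0:
            raise ValueError("rectangle needs positive dP, dV")
        m = max(2, n // 4)
        bottom = [(V0 + dV * i / m, P0) for i in range(m)]
        right = [(V0 + dV, P0 + dP * i / m) for i in range(m)]
        top = [(V0 + dV - dV * i / m, P0 + dP) for i in range(m)]
        left = [(V0, P0 + dP - dP * i / m) for i in range(m)]
        pts = bottom + right + top + left + [(V0, P0)]
        return np.array(pts)
    if shape == "ellipse":
        if a <= 0 or b <= 0:
            raise ValueError("ellipse needs positive semi-axes")
        th = np.linspace(0.0, 2.0 * math.pi, n + 1)
        return np.column_stack(
            [center[0] + a * np.cos(th), center[1] + b * np.sin(th)]
        )
    if shape == "sampled":
        if result is None:
            raise ValueError("shape='sampled' requires a SimulationResult")
        T = 60.0 / result.metrics.HR
        n_beat = int(round(T / (result.t[1] - result.t[0])))
        V = result.Y[-(n_beat + 1):, 0]
        P = result.AUX[-(n_beat + 1):, 2]
        return np.column_stack([V, P])
    raise ValueError(f"unknown loop shape {shape!r}")


# --- benchmark records -------------------------------------------------------

@dataclass
class BenchmarkRecord:
    """One expected metric value for one scenario.

    ``tolerance`` is fractional; ``tol_abs`` an absolute floor in the
    metric's own units (a match passes if within either).  ``kind`` is
    'baseline' (no-VAD steady state) or 'extremal' (speed of maximal SW over
    a sweep, tolerance in RPM).
    """

    scenario: str
    metric: str
    value: float
    tolerance: float
    source: str
    tol_abs: float = 0.0
    kind: str = "baseline"


_BASELINE_TABLE = {
    # metric: (normal, lvf, bif, lvf_pvr, bif_pvr), fractional tol, abs tol
    "CO_total": ((5.8, 3.5, 3.2, 3.3, 2.4), 0.10, 0.0),
    "EDV": ((130.0, 245.6, 237.1, 246.8, 256.0), 0.10, 0.0),
    "LAP": ((8.7, 26.0, 28.0, 19.1, 18.0), 0.10, 1.0),
    "RAP": ((4.4, 3.5, 17.1, 5.1, 20.7), 0.10, 1.5),
    "MAP": ((106.0, 77.3, 82.1, 75.9, 73.8), 0.10, 0.0),
    "PAm": ((20.1, 32.9, 37.8, 48.9, 39.8), 0.10, 0.0),
    "SV": ((68.0, 41.1, 37.1, 39.2, 28.6), 0.15, 0.0),
    "EDP": ((10.0, 25.6, 27.6, 18.8, 17.8), 0.15, 1.5),
    "RV_EDV": ((121.0, 106.4, 252.8, 125.6, 277.5), 0.15, 0.0),
    "PVR": ((2.0, 2.0, 3.1, 9.0, 9.0), 0.15, 0.3),
    "SBP": ((133.0, 95.2, 98.4, 93.0, 87.6), 0.25, 0.0),
    "DBP": ((93.0, 69.4, 74.8, 68.3, 68.0), 0.25, 0.0),
    "PAs": ((28.0, 37.9, 49.8, 61.9, 49.4), 0.25, 0.0),
    "PAd": ((15.0, 29.3, 31.7, 42.3, 35.0), 0.25, 0.0),
    "EF": ((52.0, 17.0, 16.0, 16.0, 11.0), 0.25, 5.0),
    "RV_EF": ((56.0, 39.0, 15.0, 31.0, 10.0), 0.25, 5.0),
    "RV_EDP": ((4.0, 3.3, 16.8, 4.8, 20.5), 0.25, 2.0),
    "HR": ((70.0, 85.0, 85.0, 85.0, 85.0), 0.001, 0.0),
}
_SCENARIO_ORDER = ("normal", "lvf", "bif", "lvf_pvr", "bif_pvr")


def baseline_benchmarks(
    scenarios: Sequence[str] = _SCENARIO_ORDER,
    metrics: Sequence[str] | None = None,
) -> list[BenchmarkRecord]:
    """Benchmark records for the no-VAD baselines of the five conditions."""
    records = []
    for metric, (values, tol, tol_abs) in _BASELINE_TABLE.items():
        if metrics is not None and metric not in metrics:
            continue
        for scen, val in zip(_SCENARIO_ORDER, values):
            if scen in scenarios:
                records.append(BenchmarkRecord(
                    scenario=scen, metric=metric, value=val,
                    tolerance=tol, tol_abs=tol_abs, source="baseline-table",
                ))
    return records


def extremal_benchmarks() -> list[BenchmarkRecord]:
    """Reported speeds of maximal LV stroke work, tolerance one speed step."""
    speeds = {"lvf": 9000.0, "bif": 8000.0, "lvf_pvr": 7000.0, "bif_pvr": 7000.0}
    return [
        BenchmarkRecord(scenario=s, metric="extremal_rpm", value=v,
                        tolerance=0.0, tol_abs=1000.0,
                        source="speed-sweep", kind="extremal")
        for s, v in speeds.items()
    ]


def run_benchmarks(
    scenarios: Iterable[str] | None = None,
    records: Sequence[BenchmarkRecord] | None = None,
    results: dict[str, SimulationResult] | None = None,
    sweep_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Replay scenarios against benchmark records; return a pass/fail report.

    Baseline records are compared against the converged no-VAD steady state
    of each scenario fixture (precomputed ``results`` may be supplied to
    avoid rerunning); 'extremal' records need the matching entry of
    ``sweep_tables`` (rpm/SW columns).  An empty record list yields an
    empty, trivially passing report.
    """
    if records is None:
        records = baseline_benchmarks(
            tuple(scenarios) if scenarios is not None else _SCENARIO_ORDER
        )
    results = dict(results or {})
    rows = []
    for rec in records:
        if rec.kind == "extremal":
            if sweep_tables is None or rec.scenario not in sweep_tables:
                raise KeyError(f"no sweep table supplied for {rec.scenario!r}")
            from .hemodynamic_metrics import extremal_loading

            simulated = extremal_loading(sweep_tables[rec.scenario])
        else:
            if rec.scenario not in results:
                sc = load_scenario(rec.scenario)
                results[rec.scenario] = run_to_steady_state(sc, None)
            simulated = getattr(results[rec.scenario].metrics, rec.metric)
        err = abs(simulated - rec.value)
        allowed = max(rec.tolerance * abs(rec.value), rec.tol_abs)
        rows.append({**asdict(rec), "simulated": float(simulated),
                     "error": float(err), "allowed": float(allowed),
                     "passed": bool(err <= allowed)})
    cols = ["scenario", "metric", "kind", "value", "simulated", "error",
            "tolerance", "tol_abs", "allowed", "passed", "source"]
    return pd.DataFrame(rows, columns=cols)
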
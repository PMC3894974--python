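import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cfvadsim import (
    BaroreflexParams,
    PumpParams,
    ScenarioConfig,
    SeptumParams,
    VascularParams,
    VentricleParams,
    load_scenario,
    run_to_steady_state,
    speed_sweep,
)

SWEEP_SPEEDS = tuple(range(6000, 13000, 1000))


def make_demo_scenario(**overrides) -> ScenarioConfig:
    """Generic mid-range scenario built in code (independent of fixtures)."""
    lv = VentricleParams(
        lambda_asc=2.2, lambda_desc=-1.2, V_transition=200.0, V0=10.0,
        A_ed=0.25, B_ed=0.029, Rv_coeff=2e-4, Ts_frac=0.35)
    rv = VentricleParams(
        lambda_asc=0.7, lambda_desc=-0.4, V_transition=200.0, V0=10.0,
        A_ed=0.25, B_ed=0.026, Rv_coeff=2e-4, Ts_frac=0.35)
    sc = ScenarioConfig(
        name="demo",
        lv=lv,
        rv=rv,
        septum=SeptumParams(Es_sys=48.0, Es_dia=1.0),
        vascular=VascularParams(
            R_mitral=0.0035, R_aortic=0.004, R_tricuspid=0.0025,
            R_pulmonic=0.003,
            C_sa=1.0, R_sa=0.06, L_sa=0.0003, Vu_sa=600.0,
            C_sp=2.5, R_sp=1.1, Vu_sp=250.0,
            C_sv=65.0, Vu_sv=2700.0,
            C_pa=3.5, R_pa=0.025, L_pa=0.0003, Vu_pa=90.0,
            C_pp=5.0, R_pp=0.1, Vu_pp=120.0,
            C_pv=20.0, Vu_pv=300.0,
            total_blood_volume=5400.0, heart_rate=72.0),
        baroreflex=BaroreflexParams(),
        pump=PumpParams(),
    )
    for k, v in overrides.items():
        setattr(sc, k, v)
    return sc


@pytest.fixture(scope="session")
def demo_scenario():
    return make_demo_scenario()


@pytest.fixture(scope="session")
def demo_result(demo_scenario):
    return run_to_steady_state(demo_scenario, None)


@pytest.fixture(scope="session")
def baseline_results():
    """Converged no-VAD baselines of all five shipped scenarios (+ wall time)."""
    import time

    out = {}
    for name in ("normal", "lvf", "bif", "lvf_pvr", "bif_pvr"):
        sc = load_scenario(name)
        t0 = time.perf_counter()
        res = run_to_steady_state(sc, None)
        out[name] = (res, time.perf_counter() - t0)
    return out


@pytest.fixture(scope="session")
def sweep_tables(baseline_results):
    """Speed sweeps 6k-12k RPM for the four failure scenarios."""
    import time

    tables = {}
    for name in ("lvf", "bif", "lvf_pvr", "bif_pvr"):
        sc = load_scenario(name)
        t0 = time.perf_counter()
        df = speed_sweep(sc, SWEEP_SPEEDS, baseline=baseline_results[name][0])
        df.attrs["wall"] = time.perf_counter() - t0
        tables[name] = df
    return tables


@pytest.fixture
def rng():
    return np.random.default_rng(202409)
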
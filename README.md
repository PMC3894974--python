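# cfvadsim

Closed-loop, lumped-parameter simulation of the human circulation in dilated
heart failure under continuous-flow left-ventricular-assist-device (cfVAD)
support.

## The problem

Rotary blood pumps unload the failing left ventricle continuously, and the
clinical question is *how much* unloading is desirable: too little leaves the
ventricle overdistended, too much depletes its preload and closes the aortic
valve.  Conventional simulation models give a monotone answer, because they
describe ventricular contraction with a monotonically increasing (usually
linear) end-systolic pressure-volume relationship (ESPVR).  A chronically
overloaded, dilated ventricle does not behave that way: beyond the limit of
its preload reserve, more distension produces *less* pressure — the
descending limb of the Starling response.

`cfvadsim` implements a time-varying-elastance heart whose ESPVR is
**unimodal**:

    P_es(V) = lambda_asc * (V - V0)                           for V <= V_t
    P_es(V) = lambda_asc * (V_t - V0) + lambda_desc * (V - V_t)   otherwise

(clipped at zero; `lambda_desc < 0`), embedded in a closed systemic +
pulmonary circulation with ideal-diode valves, septal interdependence
(volume displaced between LV and RV through a time-varying septal
elastance), an arterial baroreflex, and an axial cfVAD with inflow/outflow
cannulae and a suction resistor, cannulated LV apex to aorta.  Instantaneous
chamber pressure is

    P(t, V) = e(t) * P_es(V) + (1 - e(t)) * P_ed(V) - R_v * Q_eject

with activation `e(t) = sin²(pi*t / (Ts_frac*T))` during systole and the
classical exponential EDPVR `P_ed`.

With this heart, per-beat left-ventricular stroke work (SW) versus pump
speed is unimodal: moderate support recruits the ventricle back up the
descending limb and SW *rises*; further support strips preload and SW falls.
The speed at which intrinsic LV stroke work is maximal is the **extremal
loading** point — a candidate set-point for support titration and recovery
assessment.

Five calibrated conditions ship as fixtures: `normal`, `lvf` (LV failure),
`bif` (biventricular failure), and `lvf_pvr` / `bif_pvr` (the same with
pulmonary vascular resistance raised to ~9 Wood units).

## Worked example

```python
from cfvadsim import load_scenario, run_to_steady_state, speed_sweep, extremal_loading

sc = load_scenario("lvf")                    # dilated LV failure
base = run_to_steady_state(sc, None)         # no-VAD baseline
print(f"baseline: CO {base.metrics.CO_total:.1f} L/min, "
      f"EDV {base.metrics.EDV:.0f} mL, LAP {base.metrics.LAP:.1f} mmHg")

df = speed_sweep(sc, range(6000, 13000, 1000), baseline=base)
print(df[["rpm", "CO_total", "SW", "EDV", "LAP", "MAP"]].round(1))
print("extremal loading at", extremal_loading(df), "RPM")
```

prints (values from the shipped fixture; SW in gm-m/beat, volumes mL,
pressures mmHg):

```
baseline: CO 3.5 L/min, EDV 257 mL, LAP 26.2 mmHg
       rpm  CO_total    SW    EDV   LAP    MAP
0   6000.0       3.2  34.2  269.9  27.9   77.1
1   7000.0       3.8  38.7  252.9  24.8   83.4
2   8000.0       4.8  52.6  225.5  19.4   91.6
3   9000.0       5.8  65.5  190.9  13.7   99.5
4  10000.0       6.4  50.5  164.6  10.4  104.3
5  11000.0       7.0  29.7  134.3   7.4  109.4
6  12000.0       7.7  14.9   87.1   4.1  116.6
extremal loading at 9000.0 RPM
```

Reading it: the failing ventricle starts congested; ramping the pump from
6k RPM raises total output and melts the congestion (EDP and LAP fall
monotonically), while the ventricle's own stroke work first *rises* — the
pump walks the operating point back up the descending limb — and then
collapses as the pump takes over completely and the aortic valve stays
closed.  The interior stroke-work maximum is the extremal-loading speed.

A CLI wraps the same operations:

```sh
cfvadsim simulate --scenario lvf --rpm 9000 --out run.csv
cfvadsim sweep --scenario bif --rpm-min 6000 --rpm-max 12000 --rpm-step 1000 --out sweep.csv
cfvadsim report --in sweep.csv
```

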
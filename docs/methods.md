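# Methods

## Model overview

`cfvadsim` simulates the closed human circulation as a lumped-parameter
(electrical-analog) network coupled to two time-varying-elastance ventricles,
an elastic interventricular septum, a baroreflex, and an optional
continuous-flow ventricular assist device (cfVAD) cannulated from the LV apex
to the ascending aorta.

### Ventricles

Instantaneous chamber pressure is the classical superposition

    P(t, V) = e(t) · P_es(V) + (1 − e(t)) · P_ed(V) − R_v · Q_eject

with a normalized activation waveform `e(t) = sin²(π t / (Ts_frac · T))`
during systole and zero through diastole.  The squared half-sine is smooth,
starts and ends at zero, and peaks at exactly 1 — the standard choice in
elastance models when only the envelope constraints of the waveform are
known.

The end-systolic pressure-volume relationship (ESPVR) is **unimodal**: a
bilinear curve with an ascending limb of slope `lambda_asc` (the classical
Emax), a cusp at `V_transition`, and a pathological descending limb of slope
`lambda_desc < 0`, clipped at zero pressure.  A dilated, overloaded ventricle
whose loops straddle the cusp exhibits the descending limb of the Starling
response: more preload yields *less* developed pressure and stroke work.
This is the central mechanism of the package; a conventional monotone ESPVR
cannot produce the unimodal stroke-work-versus-support behaviour that
motivates extremal loading.

The end-diastolic relation (EDPVR) is the classical exponential
`P_ed = A_ed (exp(B_ed (V − V0)) − 1)`, clipped at zero below the unstressed
volume `V0`.

**Envelope floor.** At extreme dilation the clipped descending ESPVR can fall
below the exponential EDPVR.  Taken literally, the superposition then makes
activation *reduce* pressure below the passive filling pressure, which is
nonphysical (contracting muscle carries at least its passive tension) and
numerically creates a spurious stable state in which the ventricle fills
through the mitral valve at mid-systole and ejects on relaxation.  The
instantaneous pressure law therefore uses `max(P_es(V), P_ed(V))` as the
systolic envelope.  Inside the physiologic operating range the floor is
inactive and the superposition is exactly the classical form.

**Viscous loss.** Ejection incurs a Shroff-type intraventricular resistance
proportional to the instantaneous developed pressure,
`R_v = Rv_coeff · e(t) · P_es(V) / (1 mmHg)`, applied to the total outflow
(aortic valve plus pump inlet for an assisted LV).  A constant-`R_v` fallback
is available via `rv_constant`.

### Septum

Ventricular interdependence follows an interventricular-elastance
formulation: the septal displaced volume `V_spt = (P_lv − P_rv) / E_spt(e)`,
with `E_spt(e) = e·Es_sys + (1 − e)·Es_dia` sharing the LV activation,
shifts volume between the chambers; each chamber's constitutive law acts on
its free-wall volume (`V_lv − V_spt`, `V_rv + V_spt`).  Because the chamber
pressures themselves depend on the partition, each evaluation solves a
scalar fixed point; a safeguarded Newton iteration (residual < 1e-10 mmHg,
monotone in `V_spt`) converges in a handful of steps.  Transseptal pressure
is taken from the elastance components of chamber pressure (the viscous
ejection loss acts in the outflow path, not across the septal wall).

### Vascular network and valves

Systemic and pulmonary circuits each have an arterial compartment
(compliance, inertance, proximal resistance), a peripheral resistance into a
peripheral compliance, and a venous reservoir; the atria are merged into the
respective venous reservoirs.  The four valves are ideal diodes; inside the
integrator the diode characteristic is regularized over a 0.01 mmHg ramp
(`(x + √(x²+ε²))/2`) for smoothness.  Halving the ramp width changes
converged outputs by well under 0.5% (asserted in the tests).  The state
vector holds 13 circulation states (2 chamber volumes, 6 compartment
pressures, 2 inertial flows, 3 reflex effectors) plus the pump flow.

### Baroreflex

A sigmoid afferent `s = 1/(1 + exp((P_sa − P_set)/k_s))` drives three
first-order effectors: systemic peripheral resistance scale, venous
unstressed-volume shift, and ventricular contractility scale (applied to
`lambda_asc` of both ventricles).  Heart rate is held at the configured
per-condition value; the printed conditions use single fixed rates, and
clamping the chronotropic effector reproduces them exactly.

The resistance gain is **asymmetric**: `g_R_hypo = 0.62` below the setpoint
versus `g_R_hyper = 0.18` above it.  Back-solving systemic resistance from
the reported failure baselines together with the high-speed sweep endpoints
shows that all four failure conditions lie on a single static reflex curve
only if the vasoconstriction reserve far exceeds the vasodilation reserve —
which is also the shape of Ursino-type effector sigmoids.  Setpoint 95 mmHg
and width 11 mmHg are shared by every condition.

### Pump

The cfVAD characteristic is `H = β2·ω² − β0·Q − β1·dQ/dt` (outlet minus
inlet, ω in rad/s), with the printed axial-pump coefficient magnitudes
(β0 = 0.1707, β1 = 0.02177, β2 = 9.03e-5; shutoff head ≈ 80 mmHg at
9000 RPM) and equal inflow/outflow cannula resistances (0.0677 mmHg·s/mL)
and inertances (0.0127 mmHg·s²/mL).  The sign convention is chosen so the
speed head is positive — the source convention evidently measured H
inlet-minus-outlet, hence its negative speed coefficient.  A nonlinear
suction resistor `R_suc = k_suc·(P_th − P_lv)` for `P_lv ≤ P_th = 1 mmHg`
(zero above, continuous at the threshold) throttles pump inflow as the LV
approaches collapse; `k_suc` defaults to 3.5 mmHg·s/mL per mmHg, the order
of published suction-resistor gains, and is exposed in the config.
Pump speed is an exogenous piecewise-constant input; no motor dynamics.

## Numerics

The engine integrates with **fixed-step classical RK4** compiled via numba,
with the step snapped so one cardiac period is an integer number of steps
(target 1e-4 s).  This makes trajectories bit-reproducible, beat windows
exact, and the whole system fast enough to sweep interactively.  The
regularized-diode system is only mildly stiff at this step; agreement with
scipy's LSODA (max step 1 ms, rtol 1e-6, atol 1e-8) and invariance under
step halving are both asserted in the test suite.  Volume conservation is
structural (every flow appears once as inflow and once as outflow), so the
integrator's only conservation error is truncation — below 0.1 mL over a
simulated minute.

Steady state is detected on beat-aligned windows: convergence requires the
per-beat change of CO, MAP and EDV and of every state component at beat
start to fall below 0.5% (configurable), with a 200-beat cap; non-converged
runs are flagged, not raised.  Reported metrics average the five beats after
convergence.  Speed sweeps warm-start each speed from the previous converged
state; warm versus cold starts agree to < 0.5%.

End-diastolic pressures are read at beat start (pre-contraction) because the
smooth activation ramp lets filling continue slightly into early systole;
end systole for locus quantities is the activation peak (`Ts_frac·T/2`).
Stroke work converts loop area with 1 mmHg·mL = 1.33322e-4 J and
1 gm-m = 9.80665e-3 J, i.e. 0.0135951 gm-m per mmHg·mL; SWI assumes a body
surface area of 1.9 m².

## Scenario fixtures and calibration

Five conditions ship as JSON fixtures: `normal`, `lvf` (LV failure), `bif`
(biventricular failure), `lvf_pvr` and `bif_pvr` (the same with pulmonary
vascular resistance raised to ~9 Wood units).  The published per-condition
parameter tables were not available, so the fixtures were calibrated (by
bounded least squares on the converged metrics, mirroring the original
trial-and-error tuning) to reproduce the published baseline hemodynamics
and, for the failure conditions, the reported speed-sweep landmarks.  The
calibrated values are frozen in the fixtures; `calibrate_scalar` exposes the
bounded scalar search for re-tuning a designated parameter against one
metric.

Shared across all five conditions: septum (Es_sys 48, Es_dia 1 mmHg/mL),
pump, baroreflex, valve resistances, compliances, inertances and unstressed
volumes.  The four failure conditions share one failing-LV parameter set
(ascending slope 1.05 mmHg/mL, transition volume 157 mL, descending slope
−0.71 mmHg/mL, remodeled diastolic compliance) and one systemic peripheral
resistance; they differ from each other only in RV constitutive parameters
(depressed in the biventricular conditions), pulmonary resistance (raised
to ~9 Wood units in the PVR+ conditions), and total blood volume (volume
retention accompanies decompensation).  Normal versus failure additionally
differ in heart rate (70 / 85 bpm), systolic fraction (a constant ~0.30 s
absolute systolic duration: Ts_frac 0.35 at HR 70, 0.425 at HR 85) and
systemic resistance — the reported normal and failure hemodynamics are not
mutually consistent with a single static resistance-reflex curve, so the
difference in baseline vascular tone is encoded per group.

The reported normal-condition values are internally inconsistent
(CO 5.8 L/min with HR 70 and SV 68 mL implies 4.76 L/min); the normal
fixture is a compromise (CO ≈ 5.4, SV ≈ 77 mL) that keeps every headline
baseline metric within ±10%.

**Coexisting periodic states.** With a unimodal ESPVR the closed loop can
admit two stable periodic states at identical parameters: a *compensated*
state (moderate volumes, preserved ejection) and a *congested* state (the
ventricle parked on the descending limb).  Which one a simulation reaches
depends on its starting volume distribution, so `initial_state` places the
chambers in passive equilibrium with the venous pressure implied by the
configured blood volume: volume-overloaded conditions start, and stay,
congested — disease history selects the branch.  The `lvf` and `bif`
fixtures equilibrate on the congested branch at their reported operating
points.  Under a 9-Wood pulmonary bed the lungs throttle left-heart filling
and decouple LV preload from systemic volume; the mildly-congested operating
points reported for the PVR+ conditions then lie between the branches and
are not stable states of this model, so those fixtures settle on the
compensated branch: their sweep behaviour (stroke-work peak location and
magnitude, output plateau and ceiling) matches the reported response, while
several of their baseline congestion indices do not.  The same branch
structure caps the achievable stroke-work maxima in `lvf` and `bif` about
20% below the reported values: an LV strong enough to deliver them under
partial support re-compensates its own baseline.

## What the fixtures do and do not emulate

The synthetic conditions reproduce cycle-averaged pressures, volumes and
outputs of table-level clinical descriptions.  They do not represent atrial
contraction (atria are merged into venous reservoirs), valve regurgitation
(deliberately omitted to isolate the descending-limb mechanism),
renin-angiotensin volume regulation, pericardial constraint, or beat-to-beat
variability — so passing tests validate the hemodynamic coupling mechanisms,
not patient-level waveform morphology.

## Known limitations

* The bilinear-with-floor envelope makes the transition from compensated to
  decompensated operation sharp; near that boundary small parameter changes
  can move a low-speed sweep point across it.
* The baroreflex is a minimal three-effector abstraction with a clamped
  heart rate; its gains were chosen to reconcile the printed conditions, not
  fitted to open-loop reflex data.
* Pre-load-adjusted maximal power is deliberately a stub: no validated
  definition or reference values were available.
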
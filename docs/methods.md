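# Methods

This note records the model, its assumptions, the defaults that matter,
and the design decisions made where the problem was genuinely open.

## Plant model

The insufflated cavity (acrylic chamber, silicone upper-GI simulator,
or excised porcine stomach) is a single lumped isothermal ideal-gas
compartment. Wall distensibility is linear: `V = V₀ + C·P_rel` with
compliance `C` (mL/mmHg). Pump delivery is metered at atmospheric
pressure (the free-flow rating of a diaphragm pump), so conservation of
gas amount, `d(P_abs·V) = P_atm·Q_net·dt`, yields the forward-Euler
update

    ΔP_rel = P_atm · Q_net · Δt / (V + C·P_abs).

Assumptions: uniform pressure (no anatomy-resolved gradients), constant
temperature, air treated as ideal, and a proportional leak
`Q_leak = k·P_rel` when configured. Suction is clamped so absolute
pressure never falls below 5% of atmospheric, and a compliant wall may
not collapse below 5% of its resting volume; both clamps only guard
against unphysical extremes and are never active in the shipped
protocols.

Parameters and defaults:

* `base_volume` = 1000 mL — adult-stomach scale; no rig volume is
  published, so this is an order-of-magnitude choice and fully
  configurable.
* `compliance` — presets 0 (acrylic), 2 (silicone simulator), 30
  (porcine tissue) mL/mmHg. The ordering is what matters: it reproduces
  the observed contrast where the rigid-ish simulator shows sharp
  per-event fluctuations while porcine tissue absorbs bursts almost
  completely (recovery times become "n/a" on the porcine preset,
  matching the bench reports).
* `pump_max_flow` = 133.33 mL/s (8 L/min), linear PWM→flow with an
  optional deadband (default 0).
* `flow_restriction` — fraction of the free-flow rating actually
  delivered into the cavity; 1.0 by default (direct tubing, as in the
  calibration chamber), 0.1 in the rig presets. The bench rig feeds air
  through a Y-splitter and a ~2 m endoscope suction channel of a few mm
  bore; free flow through that path is not achievable. 0.1 puts the
  full-speed closed-loop slew at ≈4 mmHg/s, the scale implied by the
  published step-response times (≈3.5–3.7 s from 3.8 and 23.6 mmHg),
  and keeps the discrete derivative loop gain `Kd·G` below 1, where `G`
  (mmHg/s per PWM count) is the plant gain. Without the restriction the
  simulated loop chatters at full amplitude — an artifact of ignoring
  channel hydraulics, not a controller property.
* Integration: forward Euler at the control interval (default
  Δt = 0.0519 s, the measured acquisition cadence). Halving Δt changes
  a 1-s pressure rise by <1% (regression-tested); sub-stepping is
  unnecessary at these rates.

## Sensor model and calibration

A reading is affine-plus-noise:
`gain·P_true + offset + drift·t/3600 + N(0, σ)`. Relative pressure
subtracts a configurable zero reference (default atmospheric; the
operator may re-zero anywhere, mirroring clinical practice of
referencing the symphysis pubis or midaxillary line).

Noise defaults are split deliberately:

* **Monitoring protocol** σ = 0.8543 mmHg — the SD observed over a
  24-h open-loop bench record. That figure is dominated by slow ambient
  and drift processes, so it is the right magnitude for long open-loop
  logging.
* **Control loop** σ = 0.01 mmHg — short-term electronic noise. The
  bench system resolved pressure to two decimal places and its
  steady-state SD on the (quiet) porcine rig was ≈0.06 mmHg, so
  per-sample noise must be well below the ±0.1 mmHg recovery band;
  0.01 mmHg is consistent with both. Using the 24-h figure inside the
  loop would conflate slow drift with per-tick noise and make the
  ±0.1 mmHg criterion unmeasurable for any controller.

Calibration regresses **gauge on raw reading** (OLS via
`scipy.stats.linregress`), so applying the fitted line corrects a raw
reading; the direction is a package choice, as the source procedure
does not state one. R² is computed as `1 − SS_res/SS_tot` so that
exactly affine data yields exactly 1.0 in floating point. The sweep
applies the affine error on the gauge (relative) scale, which makes the
fitted slope/intercept directly comparable to the injected gain/offset;
composing with a fixed zero reference would only shift the intercept.
`fit_sensor_model` provides the forward regression (readings on gauge)
with standard errors for parameter-recovery studies.

## Controller

Discrete PID on the error `e = setpoint − measured`, gain-scheduled:
aggressive (40, 10.05, 20.0) for `|e| >` 2 mmHg, conservative
(4, 10.2, 40) otherwise. The 2 mmHg switching threshold and the
±0.05 mmHg stop band are package choices (neither is published); the
stop band encodes "accuracy to two decimal places" and drives the
pump-stop-at-setpoint behavior. Ties at the switching boundary resolve
to conservative (stability-preferred).

Numerical choices:

* Derivative acts on the error, initialized on the first call so a
  setpoint step produces no derivative kick; a
  derivative-on-measurement mode is available behind a config flag.
* Anti-windup: the integral is clamped so `|Ki·I| ≤ output_limit`, and
  accumulation is skipped while the output is saturated in the
  direction the error would deepen (conditional integration). A
  regression test holds overshoot under 2 mmHg after a saturated climb
  lasting tens of seconds.
* **Integrator handling at the stop band.** Default is reset-on-entry:
  when `|e|` falls inside the stop band the pumps stop and the
  integrator clears, so re-engagement starts clean. The alternative —
  freezing the integrator — retains the large charge accumulated during
  a disturbance recovery; a single noise sample outside the band then
  discharges it through the pumps and drags the pressure ~1.5 mmHg off
  target (observed in simulation). The hardware's pump stop at the
  setpoint behaves as a fresh start; `integral_reset_on_stop=False`
  restores the freezing variant.
* A single signed command is arbitrated into exclusive air/suction
  duties; the loop is one controller, not two, which matches the
  observed alternating pump activation.

The conservative gain set is, on paper, lightly damped: for a plant
gain `G` with `Kd·G ≳ 1` the small-signal loop reduces to
`ë + (Kp/Kd)ė + (Ki/Kd)e = 0`, i.e. ζ ≈ Kp/(2√(Ki·Kd)) ≈ 0.1. The
simulated loop is nonetheless well behaved because the stop band
captures the trajectory at its first zero crossing (pressure holds
exactly when the pumps stop on a leak-free plant), ending the ring-down
early. Spike recoveries settle in ≈4.8 s — same order as, though slower
than, the ≈0.8 s bench figure, whose exact value depends on hardware
details (integral discretization, motor dynamics) not published.

## Disturbances

* Cough/belch: 0.5-s external-pump bursts at ±255 PWM, ten per
  protocol, 10-s monitoring gaps ("bursts" is the reading consistent
  with the per-spike monitoring window). Injected as flow, like the
  bench's external pump. On the `gi_simulator` preset a burst moves
  pressure ~1–2 mmHg; true physiological cough pressures (>120 mmHg)
  are out of scope, as they were for the bench rig.
* Breathing: additive ±2 mmHg sinusoid at 16 cycles/min injected as a
  pressure offset (the amplitude is specified in mmHg, not flow).
* Mixed: ten coughs and ten belches at uniform random non-overlapping
  times (rejection sampling, minimum separation one burst length)
  during continuous breathing, seeded and reproducible.

## Protocols

* Calibration sweep: 24 suction levels (−100…−675 mmHg, step 25), 3-s
  stabilization per level, mean of the final 20 samples.
* Step-response suite: 19 initial pressures evenly spaced over
  3.8–23.6 mmHg (the published extreme initial values anchor the grid;
  the rig's own step increments are unspecified in any stated unit).
  Each cycle holds the pre-pressurized plant uncontrolled for 20 s,
  then regulates until 60 s total. The settling time is the elapsed
  time, from activation, of the last sample of the first 5-sample
  window whose mean is within ±0.5 mmHg of the setpoint — so a run
  starting at the setpoint reports ≈5 samples' worth of time (~0.2 s),
  the earliest evaluable window, not 0.
* Long monitoring: open-loop logging at the 0.0519 s cadence with
  Gaussian timestamp jitter (SD 0.0026 s), truncated at the exact
  duration. Tests exercise minutes, not 24 h; duration is a config
  knob and the statistics are cadence-, not length-, dependent.
* Mixed-protocol recovery times are generally "n/a": with breathing
  superimposed the pressure oscillates ~±1 mmHg, so the reach-and-
  remain ±0.1 mmHg criterion is unattainable by construction. The n/a
  marker convention mirrors the bench tables.

## Spike segmentation and statistics

Segments open where the external motor speed magnitude crosses above
50 PWM and close at the next crossing (or log end); crossings within
1 s are merged (debounce — segment ends are otherwise undefined), and
the first segment is discarded. Recovery time is a suffix scan: the
earliest sample after which every remaining sample in the segment lies
within ±0.1 mmHg of the target.

Bland–Altman: bias = sample mean of differences, SD with the n−1
denominator, SE = SD/√n, limits of agreement = bias ± 1.96·SD (the
"95% CI" naming used in some reports denotes these same limits). The
n−1 convention is confirmed by the published calibration row:
1.4001/√24 = 0.2858 matches the printed SE. Recomputing that row from
its rounded bias/SD reproduces the printed SE and upper limit exactly;
the lower limit computes to −2.5134 against a printed −2.5133, a
rounding artifact of the unrounded intermediates, which the acceptance
test asserts as computed rather than forcing.

IAH grading uses the WSACS thresholds: grade I at 12 ≤ P < 16, II at
16 ≤ P < 21, III at 21 ≤ P ≤ 25, IV above 25 mmHg.

## What the synthetic data does and does not show

The generators emulate the bench conditions: burst counts, durations
and gaps, breathing amplitude/frequency, sweep levels and averaging,
sampling cadence and jitter. They do not emulate gastric motility,
peristalsis, fluid submersion of the sensor, active muscle
contractions, temperature effects, or esophageal sphincter leak
dynamics. Passing tests therefore demonstrate the correctness of the
control law, plant arithmetic and statistics under idealized
physiology — not clinical performance on living tissue.

## Problem sizes

Shipped protocols run at full published scale (10-min disturbance
runs, 19-step suite, 24-level sweep); only the 24-h monitoring
durability test is exercised at minutes-scale durations, with duration
configurable. The whole suite completes in a few seconds.

## Known limitations

* The plant gain depends on unpublished rig properties (volume,
  channel resistance); absolute response times are scale-matched, not
  hardware-matched.
* The integral discretization of the bench controller is unknown;
  gains are interpreted in continuous-time units (PWM per mmHg,
  per mmHg·s, per mmHg/s) at the fixed cadence.
* Sensor drift is linear-in-time only; no temperature model.
* The calibration protocol, like the bench one, sweeps suction-side
  pressures while operation is at +10 mmHg; the affine model makes
  extrapolation exact by construction, which a real sensor does not
  guarantee.
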
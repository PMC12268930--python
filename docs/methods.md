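# Methods

`ventloop` is a pure-software re-creation of a dual-Venturi respiratory
sensing stack for invasive mechanical ventilation: flow metering,
calibration, breath-by-breath elastance estimation and a closed-loop
minimum-elastance set-pressure titration, exercised against a built-in
bench-lung simulator. This note records the models, the parameter choices
and the numerical decisions, including the ones that were genuinely open.

## Venturi flow model

Each Venturi converts its inlet–throat differential pressure ΔP into
volumetric flow with the classical incompressible orifice relation

    Q = c_D · A₂ · sqrt( (2ΔP/ρ) / (1 − (A₂/A₁)²) )

with discharge coefficient c_D = 0.97, air density ρ = 1.293 kg/m³ and
inlet/throat cross-sections A₁, A₂. Pressures are cmH₂O at the API
surface (98.0665 Pa per cmH₂O internally), flows L/min. The law is a pure
√ΔP relation at fixed geometry, so quartering the pressure drop halves
the flow, and it has an exact algebraic inverse, which the simulator uses
to generate sensor readings from ground-truth flow.

The inlet is the standard 22 mm respiratory-circuit bore. The throat
diameter of the physical printed part is not published; the default
(7.414 mm) is *derived* by inverting the flow law so that the
differential sensor's ±50.8 cmH₂O full scale corresponds to a 222 L/min
flow ceiling. `solve_throat_diameter` performs this inversion by
fixed-point iteration on A₂ (the contraction factor is (A₂/A₁)² ≈ 0.013,
so it converges in a handful of iterations); users who measure their own
parts can override every geometry number in the config. No
compressibility, Reynolds-number or temperature corrections are applied —
the model is the fixed-c_D incompressible law throughout.

## Sensors, zeroing, reconstruction

Three sensors: a gauge sensor at the patient Y-piece (±70.3 cmH₂O, i.e.
±1 psi) and a differential sensor per Venturi (±50.8 cmH₂O). The forward
model adds Gaussian read noise (default sd 0.05 cmH₂O — small against
the device's few-percent flow-error budget, configurable), rounds onto a
12-bit quantization grid over the sensor span (the converter width of the
device's microcontroller family; configurable or disabled entirely for
oracle runs), and saturates at full scale. Sampling is capped at 160 Hz
(the device's radio-link limit) unless device-faithful mode is disabled.

Zeroing takes the arithmetic mean of each channel over a flow-free window
of at most 10 s. A plain mean was chosen over a median or filtered
estimate: offsets are captured with the ventilator off, so the only
disturbance is sensor noise, for which the mean is efficient and its
standard error follows noise_sd/√N (property-tested).

Signed patient flow is reconstructed by clamping negative drops on each
channel to zero (that channel's one-way valve is shut), converting each
channel through the flow law, and taking inhalation minus exhalation.

**Known artifact — rectification bias near zero flow.** Because
Q ∝ √ΔP, the conversion is infinitely steep at ΔP = 0: zero-mean pressure
noise on an *idle* channel rectifies into a positive mean flow
(E[√max(ε,0)] > 0). During inspiration the idle exhalation channel
therefore subtracts a spurious ~3 L/min (at default noise), deflating
integrated inhaled volume and inflating the elastance quotient by roughly
15 % at default settings. This is a property of √-law metering with
channel-wise clamping, not an implementation bug; it cancels when both
channels are idle (the rectified means subtract) and vanishes with noise
off. It is smooth in the set pressure, so the titration's argmin — a
*comparison* between neighbouring settings — is unaffected, which the
convergence tests confirm. Users needing absolute elastance accuracy
should lower sensor noise or average more breaths.

## Lung/ventilator simulator

Ground truth is the linear single-compartment equation of motion,

    P_aw(t) = E·V(t) + R·dV/dt + PEEP,

the minimal model consistent with defining elastance as ΔP/ΔV; V is
volume above functional residual capacity. The ventilator commands an
airway-pressure waveform: exponential rise (time constant 0.05 s by
default, 0 = ideal square) to PEEP + p_set during inspiration, exponential
fall to PEEP during expiration, floored at PEEP (the expiratory PEEP
valve). A real device's rise profile is not published; the exponential
square wave is a stand-in chosen so that the waveform has a well-defined
plateau. Default settings: p_set 10, PEEP 5 cmH₂O, 15 breaths/min,
inspiratory fraction 1/3.

Elastance may be a constant or a map from set pressure to E — emulating a
bench lung whose spring is shifted — and is piecewise-constant per
simulate call (closed-loop drivers change settings at breath boundaries),
so every breath has one true E for recovery tests. Integration is
fixed-step Heun (RK2) at the sampling rate, keeping truth samples aligned
one-for-one with sensor frames; at 160 Hz and the default mechanics
(τ = R/E = 0.25 s, i.e. 40 samples per time constant) the local error is
far below every tolerance used. R = 0 is rejected (the pressure-driven
ODE degenerates). Leak (default 0 L/min) is modelled as a constant bias
flow through the inspiratory Venturi, i.e. gas escaping the circuit
downstream of the meter.

## Per-breath elastance

Breaths are segmented on the signed flow: an onset is a rising crossing
of +2 L/min held for ≥100 ms (the debounce suppresses sub-threshold
noise); a breath spans onset to next onset. Volume is the trapezoidal
integral of flow, re-zeroed at every onset so drift cannot accumulate.
Breaths shorter than 0.5 s or with tidal volume under 0.05 L are flagged
invalid (artefact filter, configurable).

The primary estimator is the endpoint quotient over the inhalation limb,
E = ΔP_inhale/ΔV_inhale. Endpoint placement matters because the gauge
pressure contains a resistive term R·Q wherever flow is nonzero:

* the *start* pressure is read one sample before the onset crossing,
  where flow is still below threshold — at the crossing sample itself the
  resistive drop is already present and biases E low by up to ~10 %;
* the limb *ends* at the last sample before flow turns expiratory
  (falls through −2 L/min), running through the end-inspiratory plateau
  where flow has decayed to near zero, rather than stopping at the
  +threshold downcrossing where ~2 L/min still flows.

With both endpoints near zero flow the resistive term vanishes and the
quotient equals the compartment E; on the noise-free grid
E ∈ {10,20,30,40} × R ∈ {2,5,10} with plateaued breaths the bias is
under 1 % (tested against 2 %). A least-squares variant (reciprocal slope
of V on P over the limb) is provided as a labelled secondary estimator:
it averages noise over the whole limb but inherits resistive bias where
flow is nonzero, so the endpoint form stays authoritative.

## Minimum-elastance titration

Each cycle queries set pressures centre ± {0, 1, 2} cmH₂O in ascending
order, holds 5 breaths per setting, aggregates per-breath E by the median
(robust to the occasional invalid breath), and moves the centre to the
argmin; ties resolve toward the current centre, then the lower pressure.
The centre can thus move at most 2 cmH₂O per cycle. Convergence is
declared after the centre survives 2 consecutive cycles unchanged.
Commanded pressures are clamped to safety bounds (default [5, 30] cmH₂O)
and a centre parked on a bound is flagged (`at_pressure_bound`): the
protocol converged to the edge of the allowed range, not to an interior
minimum. The grid step, dwell, aggregator and convergence count are all
free design parameters here — only the ±2 cmH₂O query window is fixed by
the device's protocol description — chosen so a cycle is short but
median-stable. Convergence is measured in cycles, not wall-clock time,
since the latter only restates the dwell and breathing rate.

On the reference unimodal lung (E(p) = 20 + 0.5(p−12)², R = 5) the
noise-free loop from a start of 8 cmH₂O produces the centre sequence
8 → 10 → 12 → 12 and converges; with default sensor noise, runs starting
4 cmH₂O below and above the optimum (an 8 cmH₂O start window) both
converge within one grid step of the optimum within 10 cycles.

## Apnoea and kink detection

Both are named device features without published rules; the rules here
are deliberately simple, clearly heuristic and fully configurable.
Apnoea: an event whenever a sliding window (default 10 s, re-anchored at
every breath onset) elapses with no onset. Kink: a run longer than 1 s,
during commanded inspiration, with gauge pressure above 0.8 of the
commanded inspiratory pressure while |flow| stays under 2 L/min — an
occlusion signature; raised resistance with flow still moving does not
trigger it. The kink detector needs the commanded pressure and phase,
which raw frames do not carry, so it takes the ventilator settings as an
argument.

## Problem sizes and determinism

All simulations run at 160 Hz. Recovery and equilibrium tests use 36–60 s
records (5–15 breaths); titration runs use 5-breath dwells over 5-setting
cycles and converge in ≤10 cycles, i.e. ≈20 simulated minutes per run —
sizes at which every quoted tolerance is comfortably resolved and the
whole suite runs in seconds. Every stochastic path takes an explicit seed
(default 0) through `numpy.random.default_rng`; a (config, seed) pair
fixes every output byte end-to-end, which the suite asserts. The clock
model guarantees elapsed-time arithmetic across a single wrap of the
32-bit millisecond counter only; stream readers reject records spanning
more than one wrap, mirroring the device's own 2³² ms (49 whole days)
runtime bound.

## Limitations

* Single linear compartment: no volume-dependent elastance within a
  breath, no spontaneous effort, no circuit compliance, no gas exchange —
  so PV-loop hysteresis and work-of-breathing are out of reach.
* The sensor model omits temperature drift, supply-voltage ratiometric
  effects and transport (radio) timing jitter; frames arrive on an ideal
  sample clock.
* The throat diameter is design-derived, not measured from a printed
  part; absolute flow numbers track the real device only insofar as its
  geometry matches.
* Passing tests demonstrate correctness against the simulator's
  idealized physics; they do not validate the stack against a physical
  lung or a hardware flow reference.
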
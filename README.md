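# ventloop

Dual-Venturi respiratory flow sensing, breath-by-breath elastance
estimation and closed-loop minimum-elastance pressure titration — as a
pure-software framework with a built-in lung/ventilator simulator.

`ventloop` re-creates, in software, an open-hardware sensing stack for
invasive mechanical ventilation: two Venturi flow tubes in parallel (one
per one-way valve, so inspiration and expiration each get a dedicated
differential-pressure channel) plus a gauge sensor at the patient
Y-piece. It is aimed at researchers prototyping closed-loop or
digital-twin ventilation protocols who want the full measurement chain —
sensor noise, quantization, zeroing, flow reconstruction, breath
segmentation — without bench hardware.

## The model in brief

* **Flow metering.** Each Venturi reads flow from its pressure drop via
  Q = c_D A₂ √( (2ΔP/ρ) / (1 − (A₂/A₁)²) ), with c_D = 0.97 and
  ρ = 1.293 kg/m³. With the default geometry (22 mm inlet, 7.414 mm
  throat) the differential sensor's ±50.8 cmH₂O full scale corresponds to
  a 222 L/min flow ceiling.
* **Elastance.** Per breath, E = ΔP_inhale / ΔV_inhale (cmH₂O/L): the
  reciprocal gradient of the pressure–volume loop's inhalation limb,
  evaluated between near-zero-flow endpoints.
* **Titration.** Each cycle the protocol queries set pressures within
  ±2 cmH₂O of the current setting, dwells 5 breaths per setting, and
  moves the setting to the median-elastance argmin; it converges when the
  setting stops moving.
* **Simulator.** A linear single-compartment lung
  (P_aw = E·V + R·V̇ + PEEP) ventilated by an exponential-rise
  pressure-controlled waveform, with configurable elastance-vs-pressure
  maps, sensor noise and sampling rate (≤160 Hz, the device's cap).

See `docs/methods.md` for assumptions, parameter defaults and known
artifacts (notably the √-law rectification bias of noisy near-zero flow).

## Worked example

Simulate one minute of pressure-controlled breathing (E = 20 cmH₂O/L,
R = 5 cmH₂O s/L, p_set 10 above PEEP 5, 15 breaths/min), then process the
raw sensor stream back into breaths:

```sh
$ ventloop simulate --duration 60 --seed 0 --out breaths_raw.csv
wrote 9601 frames to breaths_raw.csv
$ ventloop process breaths_raw.csv --breaths-out breaths.csv
15 breaths (15 valid), median elastance 23.41 cmH2O/L
$ head -4 breaths.csv
breath_idx,onset_ms,tv_l,dp_inhale_cmh2o,dv_inhale_l,elastance_cmh2o_per_l,valid
0,6.250,0.4470,9.9546,0.4236,23.4991,1
1,4000.000,0.4425,10.0233,0.4304,23.2861,1
2,8006.250,0.4478,10.0233,0.4281,23.4111,1
```

Sixty seconds at 15 breaths/min yields 15 breaths of ~0.45 L tidal
volume (the true equilibrium is p_set/E = 0.5 L; the shortfall is the
default sensor noise rectifying through the √-law flow conversion — see
the methods note). The median elastance of 23.4 cmH₂O/L carries the same
noise-induced upward bias; rerun with `--noise-sd 0` and the estimate
lands within 1 % of the true 20.

Closed-loop titration on a lung whose elastance is minimal at a set
pressure of 12 cmH₂O, starting 4 cmH₂O low:

```sh
$ ventloop titrate --start-pressure 8 --optimum-pressure 12 --seed 0 --out titration.csv
converged at centre 12.0 cmH2O after 6 cycles
$ head -6 titration.csv
cycle,centre_cmh2o,setting_cmh2o,elastance_est,argmin,converged
0,8.0000,6.0000,46.7559,0,1
0,8.0000,7.0000,39.2919,0,1
0,8.0000,8.0000,33.4770,0,1
0,8.0000,9.0000,28.3496,0,1
0,8.0000,10.0000,25.4225,1,1
```

The first cycle queries 6–10 cmH₂O, finds the minimum measured elastance
at its upper edge (10, flagged `argmin`), and moves the centre there; the
loop walks 8 → 10 → 12 and parks.

The same pipeline is available as a library (`ventloop.simulate`,
`ventloop.reconstruct_flow`, `ventloop.extract_breaths`,
`ventloop.run_titration`, ...), which is what the test suite exercises.

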
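"""Single-compartment lung + pressure-controlled ventilator simulator.

Synthetic ground truth standing in for a bench mechanical lung driven by a
pressure-controlled ventilator through the dual-Venturi circuit.  The lung
obeys the linear single-compartment equation of motion

    P_aw(t) = E * V(t) + R * dV/dt + PEEP

with volume V above functional residual capacity, elastance E (cmH2O/L)
and resistance R (cmH2O s/L).  The ventilator commands an airway-pressure
waveform: exponential rise to PEEP + p_set during inspiration, exponential
fall back to PEEP during expiration, floored at PEEP (the expiratory PEEP
valve).  Elastance may depend on the ventilator set pressure — emulating a
bench lung whose spring is shifted between runs — and is held
piecewise-constant per breath so every breath has a well-defined true E.

Integration is fixed-step Heun (RK2) at the sampling rate, keeping truth
streams aligned sample-for-sample with the generated sensor frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .sensing import (
    FrameStream,
    MAX_SAMPLE_RATE_HZ,
    SensorSpec,
    default_sensor_bank,
    dp_from_flow_array,
    quantize_and_noise,
)
from .venturi import GasProperties, VenturiGeometry

ElastanceMap = Callable[[float], float]


@dataclass
class LungParams:
    """Ground-truth lung: elastance (map or constant), resistance, leak.

    ``elastance`` is either a constant in cmH2O/L or a callable mapping the
    ventilator set pressure (cmH2O above PEEP) to elastance, emulating the
    pressure-dependent stiffness of a recruitable lung.  ``resistance`` is
    in cmH2O s/L.  ``leak`` (L/min, default 0) is a constant bias flow
    through the inspiratory Venturi from gas escaping the circuit.
    """

    elastance: float | ElastanceMap = 20.0
    resistance: float = 5.0
    leak: float = 0.0

    def __post_init__(self) -> None:
        if self.resistance < 0:
            raise ValueError("resistance must be >= 0")
        if not callable(self.elastance) and self.elastance <= 0:
            raise ValueError("elastance must be > 0")

    def elastance_at(self, p_set: float) -> float:
        e = self.elastance(p_set) if callable(self.elastance) else float(self.elastance)
        if e <= 0:
            raise ValueError(f"elastance map returned non-positive E={e} at p_set={p_set}")
        return e


def shift_spring(lung: LungParams, elastance: float | ElastanceMap) -> LungParams:
    """Return the lung with a new elastance map (the bench 'spring shift').

    Validation of a callable map is deferred to the pressures actually
    queried; running simulations pick the new map up at the next breath
    boundary because elastance is sampled per breath.
    """
    if not callable(elastance) and elastance <= 0:
        raise ValueError("elastance must be > 0")
    return replace(lung, elastance=elastance)


@dataclass
class VentSettings:
    """Pressure-controlled ventilator settings.

    ``p_set`` is the inspiratory pressure above PEEP (driving pressure
    target, cmH2O); ``rate`` in breaths/min; ``i_fraction`` the inspiratory
    fraction of the cycle; ``rise_time_constant`` (s) shapes the
    exponential pressure rise/fall (0 = ideal square wave).
    """

    p_set: float = 10.0
    peep: float = 5.0
    rate: float = 15.0
    i_fraction: float = 1.0 / 3.0
    rise_time_constant: float = 0.05

    def __post_init__(self) -> None:
        if self.p_set < 0:
            raise ValueError("p_set must be >= 0")
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if not self.rate > 0:
            raise ValueError("rate must be > 0")
        if not (0.0 < self.i_fraction < 1.0):
            raise ValueError("i_fraction must be in (0, 1)")
        if self.rise_time_constant < 0:
            raise ValueError("rise_time_constant must be >= 0")

    @property
    def period_s(self) -> float:
        return 60.0 / self.rate

    @property
    def t_insp_s(self) -> float:
        return self.period_s * self.i_fraction


@dataclass
class SimTrace:
    """Aligned truth streams and the raw sensor frames derived from them."""

    t_ms: np.ndarray          # sample times, ms from run start
    p_aw: np.ndarray          # true airway pressure at the Y-piece, cmH2O
    q_lpm: np.ndarray         # true patient flow, L/min, + = inspiration
    v_l: np.ndarray           # true volume above FRC, L
    e_active: np.ndarray      # true elastance of the breath each sample is in
    frames: FrameStream       # raw frames after the sensor model
    v_end: float = 0.0        # final volume, for chaining runs


def commanded_pressure(vent: VentSettings, t_in_cycle: np.ndarray) -> np.ndarray:
    """Commanded airway pressure over one cycle's local time axis (s).

    Exponential rise toward PEEP + p_set for t < t_insp, exponential decay
    back toward PEEP after; never below PEEP (PEEP valve floor).
    """
    tau = vent.rise_time_constant
    ti = vent.t_insp_s
    p = np.empty_like(t_in_cycle)
    insp = t_in_cycle < ti
    if tau == 0.0:
        p[insp] = vent.peep + vent.p_set
        p[~insp] = vent.peep
    else:
        p[insp] = vent.peep + vent.p_set * (1.0 - np.exp(-t_in_cycle[insp] / tau))
        p_end = vent.p_set * (1.0 - math.exp(-ti / tau))
        p[~insp] = vent.peep + p_end * np.exp(-(t_in_cycle[~insp] - ti) / tau)
    return np.maximum(p, vent.peep)


def simulate(
    lung: LungParams,
    vent: VentSettings,
    duration_s: float,
    fs: float = MAX_SAMPLE_RATE_HZ,
    seed: int | np.random.Generator = 0,
    sensors: dict[str, SensorSpec] | None = None,
    geom: VenturiGeometry | None = None,
    gas: GasProperties | None = None,
    v0: float = 0.0,
    t0_ms: float = 0.0,
    device_faithful: bool = True,
) -> SimTrace:
    """Simulate ``duration_s`` seconds of pressure-controlled ventilation.

    Integrates dV/dt = (P_aw - PEEP - E V) / R with fixed-step Heun at the
    sampling rate, evaluates the commanded waveform analytically at sample
    and half-sample times, routes flow through the correct Venturi channel
    (the other channel's one-way valve is shut, dp = 0) and applies the
    forward sensor model.  Deterministic for a fixed seed.

    ``v0``/``t0_ms`` allow chaining runs (closed-loop protocols change
    settings at breath boundaries and continue from the last state).

    Raises
    ------
    ValueError
        If ``fs`` exceeds the 160 Hz device cap in device-faithful mode, or
        resistance is zero (degenerate ODE).
    """
    if device_faithful and fs > MAX_SAMPLE_RATE_HZ:
        raise ValueError(f"fs={fs} Hz exceeds the device cap of {MAX_SAMPLE_RATE_HZ:.0f} Hz")
    if fs <= 0 or duration_s <= 0:
        raise ValueError("fs and duration_s must be > 0")
    if lung.resistance == 0.0:
        raise ValueError("resistance must be > 0 for the pressure-controlled ODE")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sensors = sensors if sensors is not None else default_sensor_bank()
    geom = geom or VenturiGeometry()
    gas = gas or GasProperties()

    n = int(round(duration_s * fs)) + 1
    dt = 1.0 / fs
    t_s = np.arange(n) * dt
    period = vent.period_s

    t_cycle = np.mod(t_s, period)
    p_cmd = commanded_pressure(vent, t_cycle)
    t_cycle_half = np.mod(t_s[:-1] + 0.5 * dt, period)
    p_cmd_half = commanded_pressure(vent, t_cycle_half)

    # elastance is sampled per run at the active set pressure; closed-loop
    # callers change p_set only at breath boundaries, so within any one
    # simulate() call every breath shares this true E
    e_true = lung.elastance_at(vent.p_set)
    e_active = np.full(n, e_true)

    r = lung.resistance
    peep = vent.peep
    v = np.empty(n)
    v[0] = v0
    pc = p_cmd
    pch = p_cmd_half
    vi = v0
    for i in range(n - 1):
        e = e_active[i]
        k1 = (pc[i] - peep - e * vi) / r
        k2 = (pch[i] - peep - e * (vi + 0.5 * dt * k1)) / r
        vi = vi + dt * k2
        v[i + 1] = vi

    # truth flow from the ODE's own right-hand side (exact at sample times)
    q_lps = (pc - peep - e_active * v) / r
    q_lpm = q_lps * 60.0

    q_in = np.maximum(q_lpm, 0.0) + lung.leak
    q_ex = np.maximum(-q_lpm, 0.0)
    dp_in_truth = dp_from_flow_array(np.maximum(q_in, 0.0), geom, gas)
    dp_ex_truth = dp_from_flow_array(q_ex, geom, gas)

    frames = FrameStream(
        t_ms=t0_ms + t_s * 1000.0,
        p_gauge=quantize_and_noise(p_cmd, sensors["p_gauge"], rng),
        dp_in=quantize_and_noise(dp_in_truth, sensors["dp_in"], rng),
        dp_ex=quantize_and_noise(dp_ex_truth, sensors["dp_ex"], rng),
    )
    return SimTrace(
        t_ms=t0_ms + t_s * 1000.0,
        p_aw=p_cmd,
        q_lpm=q_lpm,
        v_l=v,
        e_active=e_active,
        frames=frames,
        v_end=float(v[-1]),
    )
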
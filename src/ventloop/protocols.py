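"""Closed-loop minimum-elastance titration and safety-event detectors.

The titration protocol searches for the ventilator set pressure that
minimizes the measured respiratory elastance — the pressure at which the
lung is most compliant.  Each cycle it queries a grid of settings within
+/-2 cmH2O of the current centre, dwells a few breaths at each, aggregates
the per-breath elastance estimates by the median, and moves the centre to
the grid argmin.  The centre therefore moves at most one half-window per
cycle; on a unimodal elastance-pressure relationship the centre walks to
the optimum and parks there, and the protocol declares convergence after
the centre survives a configurable number of cycles unchanged.

The apnoea and kink detectors are deliberately simple, configurable
heuristics (the device exposes them as optional monitoring hooks):
apnoea = no breath onset within a sliding window; kink = sustained
near-command pressure with near-zero flow during commanded inspiration,
the signature of an occluded circuit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol

import numpy as np

from .breaths import extract_breaths
from .sensing import (
    FlowStream,
    FrameStream,
    apply_calibration,
    default_sensor_bank,
    mark_zeroed,
    reconstruct_flow,
)
from .simulator import LungParams, VentSettings, simulate
from .venturi import GasProperties, VenturiGeometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TitrationConfig:
    """Tunables of the minimum-elastance search.

    ``query_halfwidth`` (cmH2O) is the half-width of the per-cycle query
    window; ``grid_step`` its resolution; ``breaths_per_setting`` the dwell
    at each setting; aggregation is the median of valid per-breath
    estimates.  ``convergence_k`` consecutive cycles with an unchanged
    centre declare convergence.  ``pressure_bounds`` are safety clamps on
    any commanded set pressure.
    """

    query_halfwidth: float = 2.0
    grid_step: float = 1.0
    breaths_per_setting: int = 5
    convergence_k: int = 2
    max_cycles: int = 20
    pressure_bounds: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        if not (0 < self.grid_step <= self.query_halfwidth):
            raise ValueError("require 0 < grid_step <= query_halfwidth")
        if self.breaths_per_setting < 1:
            raise ValueError("breaths_per_setting must be >= 1")
        if self.convergence_k < 1:
            raise ValueError("convergence_k must be >= 1")
        lo, hi = self.pressure_bounds
        if not lo < hi:
            raise ValueError("pressure_bounds must satisfy lo < hi")

    def grid(self, centre: float) -> list[float]:
        """Ascending query grid centre +/- {0, step, ..., halfwidth}, clamped."""
        lo, hi = self.pressure_bounds
        n = int(round(self.query_halfwidth / self.grid_step))
        raw = [centre + k * self.grid_step for k in range(-n, n + 1)]
        clamped = []
        for p in raw:
            pc = min(max(p, lo), hi)
            if pc != p:
                logger.warning("titration setting %.2f clamped to %.2f (safety bounds)", p, pc)
            if pc not in clamped:
                clamped.append(pc)
        return clamped


@dataclass
class CycleRecord:
    """One titration cycle: the settings queried and the aggregate E at each."""

    cycle: int
    centre: float
    elastance_by_setting: dict[float, float]
    new_centre: float


@dataclass
class TitrationState:
    """Mutable protocol state: current centre, last cycle's map, convergence."""

    centre: float
    cycle: int = 0
    unchanged_streak: int = 0
    converged: bool = False
    last_map: dict[float, float] = field(default_factory=dict)
    trajectory: list[CycleRecord] = field(default_factory=list)


@dataclass
class TitrationResult:
    """Outcome of :func:`run_titration`.

    ``at_pressure_bound`` flags a centre parked on a safety bound: the
    protocol is formally converged there, but the parked setting is the
    edge of the allowed range, not an interior elastance minimum.
    """

    state: TitrationState
    converged: bool
    cycles_used: int
    pressure_bounds: tuple[float, float] = (5.0, 30.0)

    @property
    def centre(self) -> float:
        return self.state.centre

    @property
    def at_pressure_bound(self) -> bool:
        return self.state.centre in self.pressure_bounds

    @property
    def trajectory(self) -> list[CycleRecord]:
        return self.state.trajectory


class VentInterface(Protocol):
    """A ventilator that can hold a set pressure for a number of breaths.

    ``hold`` commands the set pressure, waits ``n_breaths`` breaths, and
    returns the raw sensor frames captured over that dwell.
    """

    def hold(self, p_set: float, n_breaths: int) -> FrameStream: ...


@dataclass
class SimulatedVentilator:
    """A :class:`VentInterface` backed by the lung/ventilator simulator.

    Carries lung volume and clock across holds so settings change at breath
    boundaries of one continuous record, like a bench run.  Deterministic
    under a fixed seed.
    """

    lung: LungParams
    vent: VentSettings
    fs: float = 160.0
    seed: int = 0
    noise_sd: float = 0.05
    quantization_bits: int | None = 12
    geom: VenturiGeometry = field(default_factory=VenturiGeometry)
    gas: GasProperties = field(default_factory=GasProperties)

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self._v = 0.0
        self._t_ms = 0.0
        self.sensors = default_sensor_bank(self.noise_sd, self.quantization_bits)
        mark_zeroed(self.sensors)  # simulator sensors have true zero offsets

    def hold(self, p_set: float, n_breaths: int) -> FrameStream:
        vent = replace(self.vent, p_set=p_set)
        trace = simulate(
            self.lung, vent,
            duration_s=n_breaths * vent.period_s,
            fs=self.fs, seed=self._rng, sensors=self.sensors,
            geom=self.geom, gas=self.gas,
            v0=self._v, t0_ms=self._t_ms,
        )
        self._v = trace.v_end
        # drop the shared endpoint sample so consecutive holds concatenate
        self._t_ms = float(trace.t_ms[-1]) + 1000.0 / self.fs
        return trace.frames


def estimate_setting_elastance(frames: FrameStream, vent_iface: SimulatedVentilator) -> float:
    """Median per-breath elastance over one dwell's raw frames.

    Calibrates, reconstructs signed flow, segments breaths and aggregates
    the valid estimates; NaN when no breath in the dwell is valid.
    """
    cal = apply_calibration(frames, vent_iface.sensors)
    flow = reconstruct_flow(cal, vent_iface.geom, vent_iface.gas)
    breaths = extract_breaths(flow)
    vals = [b.elastance for b in breaths if b.valid]
    if not vals:
        return float("nan")
    return float(np.median(vals))


Estimator = Callable[[FrameStream], float]


def _argmin_setting(emap: dict[float, float], centre: float) -> float:
    """Grid argmin with ties toward the current centre, then lower pressure."""
    finite = {p: e for p, e in emap.items() if np.isfinite(e)}
    if not finite:
        return centre
    emin = min(finite.values())
    ties = [p for p, e in finite.items() if e == emin]
    ties.sort(key=lambda p: (abs(p - centre), p))
    return ties[0]


def titration_cycle(state: TitrationState, config: TitrationConfig,
                    vent_iface: VentInterface,
                    estimator: Estimator | None = None) -> TitrationState:
    """Run one query cycle and move the centre to the measured argmin.

    Queries each grid setting in ascending order, dwells
    ``breaths_per_setting`` breaths, records the aggregated elastance, then
    updates the centre (ties resolve toward the current centre, then the
    lower pressure).  Settings where every breath is invalid are skipped
    with a warning.  Updates the convergence streak.
    """
    if estimator is None:
        estimator = lambda frames: estimate_setting_elastance(frames, vent_iface)  # noqa: E731
    emap: dict[float, float] = {}
    for p in config.grid(state.centre):
        frames = vent_iface.hold(p, config.breaths_per_setting)
        e = estimator(frames)
        if not np.isfinite(e):
            logger.warning("all breaths invalid at setting %.2f cmH2O; setting skipped", p)
            continue
        emap[p] = e
    new_centre = _argmin_setting(emap, state.centre)
    state.trajectory.append(CycleRecord(state.cycle, state.centre, dict(emap), new_centre))
    state.unchanged_streak = state.unchanged_streak + 1 if new_centre == state.centre else 0
    state.centre = new_centre
    state.last_map = emap
    state.cycle += 1
    if state.unchanged_streak >= config.convergence_k:
        state.converged = True
    return state


def run_titration(vent_iface: VentInterface, config: TitrationConfig,
                  start_centre: float) -> TitrationResult:
    """Iterate titration cycles until convergence or ``max_cycles``.

    Non-convergence is reported in the result, not raised.  Determinism
    follows from the ventilator interface's own seed.
    """
    lo, hi = config.pressure_bounds
    state = TitrationState(centre=min(max(start_centre, lo), hi))
    for _ in range(config.max_cycles):
        titration_cycle(state, config, vent_iface)
        if state.converged:
            break
    return TitrationResult(state=state, converged=state.converged,
                           cycles_used=state.cycle,
                           pressure_bounds=config.pressure_bounds)


@dataclass(frozen=True)
class ApnoeaEvent:
    """An apnoea alarm: no breath onset for a full detection window."""

    window_start_ms: float
    raised_at_ms: float


def detect_apnoea(flow: FlowStream, window_s: float = 10.0,
                  onsets: list[int] | None = None) -> list[ApnoeaEvent]:
    """Apnoea events: every elapsed window with no breath onset raises one.

    The window slides from the stream start or the most recent onset
    (whichever is later); an event is raised each time a full window passes
    without an onset, carrying the window's start tick.
    """
    from .breaths import segment_breaths

    if len(flow) == 0:
        return []
    if onsets is None:
        onsets = segment_breaths(flow)
    onset_times = [flow.t_ms[i] for i in onsets]
    window_ms = window_s * 1000.0
    events: list[ApnoeaEvent] = []
    anchor = float(flow.t_ms[0])
    j = 0
    t_end = float(flow.t_ms[-1])
    while anchor + window_ms <= t_end:
        # any onset inside (anchor, anchor+window] re-anchors the window
        nxt = None
        while j < len(onset_times):
            if anchor < onset_times[j] <= anchor + window_ms:
                nxt = float(onset_times[j])
                j += 1
                break
            if onset_times[j] <= anchor:
                j += 1
            else:
                break
        if nxt is not None:
            anchor = nxt
            continue
        events.append(ApnoeaEvent(window_start_ms=anchor, raised_at_ms=anchor + window_ms))
        anchor = anchor + window_ms
    return events


@dataclass(frozen=True)
class KinkEvent:
    """A suspected circuit occlusion: pressure at command, flow absent."""

    start_ms: float
    end_ms: float


def detect_kink(flow: FlowStream, vent: VentSettings,
                pressure_fraction: float = 0.8,
                flow_floor_lpm: float = 2.0,
                hold_s: float = 1.0) -> list[KinkEvent]:
    """Occlusion heuristic on a calibrated flow/pressure stream.

    Flags maximal runs where, during commanded inspiration, gauge pressure
    exceeds ``pressure_fraction`` of the commanded inspiratory pressure
    (PEEP + p_set) while |flow| stays below ``flow_floor_lpm``, lasting
    longer than ``hold_s``.  High resistance with flow still present does
    not trigger (flow condition fails).  Inspiratory phase is derived from
    the ventilator timing.
    """
    if len(flow) == 0:
        return []
    t_s = flow.t_ms / 1000.0
    phase = np.mod(t_s - t_s[0], vent.period_s)
    insp = phase < vent.t_insp_s
    p_target = vent.peep + vent.p_set
    cond = insp & (flow.p_gauge >= pressure_fraction * p_target) \
        & (np.abs(flow.q_lpm) < flow_floor_lpm)
    events: list[KinkEvent] = []
    i = 0
    n = len(cond)
    hold_ms = hold_s * 1000.0
    while i < n:
        if cond[i]:
            j = i
            while j + 1 < n and cond[j + 1]:
                j += 1
            if flow.t_ms[j] - flow.t_ms[i] > hold_ms:
                events.append(KinkEvent(float(flow.t_ms[i]), float(flow.t_ms[j])))
            i = j + 1
        else:
            i += 1
    return events
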
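"""Sensor models, zeroing/calibration, and signed-flow reconstruction.

The device carries three pressure sensors: a gauge sensor at the patient
Y-piece (+/-70.3 cmH2O, i.e. +/-1 psi) and one differential sensor across
each Venturi (+/-50.8 cmH2O).  One-way valves route inspiration through one
Venturi and expiration through the other, so each differential channel sees
only non-negative drops when its valve is open; a negative reading is valve
leak-back or noise and is clamped to zero during flow reconstruction.

The forward sensor model (used by the simulator) adds Gaussian noise,
rounds onto a 12-bit quantization grid over the sensor span, and saturates
at full scale.  Zeroing captures per-channel offsets as the plain mean of a
short flow-free window (at most 10 s, the device's own budget) and must
happen before calibration is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .venturi import GasProperties, VenturiGeometry, flow_from_dp

MAX_SAMPLE_RATE_HZ = 160.0
"""Device cap on sampling rate (BLE transmission limit)."""

MAX_ZEROING_S = 10.0
"""Zeroing window budget in seconds."""

GAUGE_FULL_SCALE_CMH2O = 70.3  # +/-1 psi gauge sensor
DIFF_FULL_SCALE_CMH2O = 50.8

CHANNELS = ("p_gauge", "dp_in", "dp_ex")


@dataclass
class SensorSpec:
    """One pressure sensor: range, quantization, noise and zero-offset state.

    Parameters
    ----------
    full_scale
        Symmetric range in cmH2O; readings saturate at +/-full_scale.
    quantization_bits
        ADC width over the 2*full_scale span; ``None`` disables quantization
        (ideal sensor, used for noise-free oracle runs).
    noise_sd
        Gaussian read-noise standard deviation, cmH2O.
    zero_offset
        Additive offset state, captured by :func:`zero_sensors`.
    """

    full_scale: float = DIFF_FULL_SCALE_CMH2O
    quantization_bits: int | None = 12
    noise_sd: float = 0.05
    zero_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.full_scale > 0:
            raise ValueError("full_scale must be > 0")
        if self.quantization_bits is not None and self.quantization_bits < 1:
            raise ValueError("quantization_bits must be >= 1 or None")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def quantization_step(self) -> float:
        """Grid step in cmH2O: 2*full_scale / 2**bits (0.0 if unquantized)."""
        if self.quantization_bits is None:
            return 0.0
        return 2.0 * self.full_scale / (1 << self.quantization_bits)


def default_sensor_bank(noise_sd: float = 0.05,
                        quantization_bits: int | None = 12) -> dict[str, SensorSpec]:
    """The device's three sensors keyed by channel name."""
    return {
        "p_gauge": SensorSpec(GAUGE_FULL_SCALE_CMH2O, quantization_bits, noise_sd),
        "dp_in": SensorSpec(DIFF_FULL_SCALE_CMH2O, quantization_bits, noise_sd),
        "dp_ex": SensorSpec(DIFF_FULL_SCALE_CMH2O, quantization_bits, noise_sd),
    }


@dataclass(frozen=True)
class SampleFrame:
    """One timestamped raw sensor reading (all pressures in cmH2O)."""

    t: float  # device clock tick, ms
    p_gauge: float
    dp_in: float
    dp_ex: float


@dataclass
class FrameStream:
    """Columnar stream of sample frames (the package's working container).

    ``t_ms`` must be strictly increasing (single clock wrap handled by the
    stream reader); pressures are raw or calibrated cmH2O depending on the
    ``calibrated`` flag.
    """

    t_ms: np.ndarray
    p_gauge: np.ndarray
    dp_in: np.ndarray
    dp_ex: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        n = len(self.t_ms)
        for name in ("p_gauge", "dp_in", "dp_ex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length != time axis length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    def frames(self) -> list[SampleFrame]:
        return [
            SampleFrame(float(t), float(pg), float(di), float(de))
            for t, pg, di, de in zip(self.t_ms, self.p_gauge, self.dp_in, self.dp_ex)
        ]


@dataclass
class FlowStream:
    """Signed patient flow reconstructed from the two Venturi channels.

    ``q_lpm`` is positive during inspiration.  ``v_l`` (volume above breath
    onset, litres) is NaN until breath segmentation/integration fills it.
    """

    t_ms: np.ndarray
    q_lpm: np.ndarray
    p_gauge: np.ndarray
    v_l: np.ndarray = field(default=None)  # type: ignore[assignment]
    breath_idx: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.v_l is None:
            self.v_l = np.full_like(self.q_lpm, np.nan, dtype=float)
        if self.breath_idx is None:
            self.breath_idx = np.full(len(self.q_lpm), -1, dtype=int)

    def __len__(self) -> int:
        return len(self.t_ms)


def zero_sensors(stream: FrameStream, specs: dict[str, SensorSpec],
                 max_duration_s: float = MAX_ZEROING_S) -> dict[str, float]:
    """Capture per-channel zero offsets from a flow-free window.

    The offset of each channel is its arithmetic mean over the window; the
    offsets are stored into ``specs`` (mutated in place) and returned.  The
    caller guarantees the stream was captured with the ventilator off — the
    routine cannot tell flow from offset.

    Raises
    ------
    ValueError
        If the stream is empty or spans more than ``max_duration_s``
        (default 10 s, the device budget).
    """
    if len(stream) == 0:
        raise ValueError("cannot zero on an empty stream")
    span_s = (stream.t_ms[-1] - stream.t_ms[0]) / 1000.0
    if span_s > max_duration_s:
        raise ValueError(
            f"zeroing window {span_s:.2f}s exceeds the {max_duration_s:.0f}s budget"
        )
    offsets = {
        "p_gauge": float(np.mean(stream.p_gauge)),
        "dp_in": float(np.mean(stream.dp_in)),
        "dp_ex": float(np.mean(stream.dp_ex)),
    }
    for ch, off in offsets.items():
        specs[ch].zero_offset = off
        specs[ch]._zeroed = True  # type: ignore[attr-defined]
    return offsets


def mark_zeroed(specs: dict[str, SensorSpec]) -> None:
    """Declare factory-zeroed sensors (offsets already correct, e.g. simulator)."""
    for spec in specs.values():
        spec._zeroed = True  # type: ignore[attr-defined]


def _is_zeroed(spec: SensorSpec) -> bool:
    return getattr(spec, "_zeroed", False)


def apply_calibration(stream: FrameStream, specs: dict[str, SensorSpec]) -> FrameStream:
    """Subtract stored offsets channel-wise and saturate at each full scale.

    Requires :func:`zero_sensors` (or :func:`mark_zeroed`) to have run.
    """
    for ch in CHANNELS:
        if not _is_zeroed(specs[ch]):
            raise RuntimeError("sensors are not zeroed; run zero_sensors first")
    out = {}
    for ch in CHANNELS:
        spec = specs[ch]
        vals = getattr(stream, ch) - spec.zero_offset
        out[ch] = np.clip(vals, -spec.full_scale, spec.full_scale)
    return FrameStream(stream.t_ms.copy(), out["p_gauge"], out["dp_in"], out["dp_ex"],
                       calibrated=True)


def reconstruct_flow(stream: FrameStream,
                     geom: VenturiGeometry | None = None,
                     gas: GasProperties | None = None) -> FlowStream:
    """Signed patient flow from the calibrated dual-Venturi channels.

    Negative drops on either channel mean that channel's one-way valve is
    shut and are clamped to zero; each channel is converted through the
    Venturi equation and the signed flow is inhalation minus exhalation.
    With ideal valves at most one channel is nonzero per sample; if noise
    makes both nonzero, the difference is still taken.
    """
    if not stream.calibrated:
        raise ValueError("reconstruct_flow requires a calibrated stream")
    geom = geom or VenturiGeometry()
    gas = gas or GasProperties()
    q_in = _flow_from_dp_array(np.maximum(stream.dp_in, 0.0), geom, gas)
    q_ex = _flow_from_dp_array(np.maximum(stream.dp_ex, 0.0), geom, gas)
    return FlowStream(stream.t_ms.copy(), q_in - q_ex, stream.p_gauge.copy())


def _flow_from_dp_array(dp: np.ndarray, geom: VenturiGeometry,
                        gas: GasProperties) -> np.ndarray:
    # vectorised flow_from_dp; dp already clamped >= 0
    scale = flow_from_dp(1.0, geom, gas)  # sqrt-law: Q(dp) = Q(1)*sqrt(dp)
    return scale * np.sqrt(dp)


def dp_from_flow_array(q: np.ndarray, geom: VenturiGeometry,
                       gas: GasProperties) -> np.ndarray:
    """Vectorised inverse Venturi law for non-negative flow arrays (L/min)."""
    from .venturi import dp_from_flow

    scale = dp_from_flow(1.0, geom, gas)  # dp(q) = dp(1)*q^2
    return scale * np.square(q)


def quantize_and_noise(truth, spec: SensorSpec, rng: np.random.Generator):
    """Forward sensor model: truth -> noisy, quantized, saturated reading.

    Adds Gaussian noise of sd ``spec.noise_sd``, rounds to the quantization
    grid (multiples of ``spec.quantization_step``), and clamps to
    +/-``spec.full_scale``.  Deterministic for a fixed generator state.
    Accepts scalars or arrays.
    """
    x = np.asarray(truth, dtype=float)
    scalar = x.ndim == 0
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
    step = spec.quantization_step
    if step > 0:
        x = np.round(x / step) * step
    x = np.clip(x, -spec.full_scale, spec.full_scale)
    return float(x) if scalar else x
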
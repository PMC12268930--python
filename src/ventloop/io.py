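"""CSV stream dialects and run configuration.

Two stream dialects mirror the device's data path (UTF-8, "." decimal, no
thousands separators):

* raw:      ``t_ms,p_gauge_cmh2o,dp_in_cmh2o,dp_ex_cmh2o``
* derived:  ``t_ms,p_gauge_cmh2o,q_lpm,v_l,breath_idx``

plus a per-breath table and a titration trajectory log.  Formatting is
deterministic (pressures and volumes 4 decimals, flows 2, times 3), so a
write -> read -> write round trip is byte-identical and a fixed-seed
simulator run always produces the same bytes.

Raw timestamps are ticks of the device's 32-bit ms clock; the reader
unwraps at most one counter wrap and rejects streams spanning more.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breaths import Breath
from .protocols import TitrationConfig, TitrationResult
from .sensing import FlowStream, FrameStream, MAX_SAMPLE_RATE_HZ
from .units import CLOCK_WRAP_MS
from .venturi import GasProperties, VenturiGeometry

logger = logging.getLogger(__name__)

RAW_HEADER = ["t_ms", "p_gauge_cmh2o", "dp_in_cmh2o", "dp_ex_cmh2o"]
DERIVED_HEADER = ["t_ms", "p_gauge_cmh2o", "q_lpm", "v_l", "breath_idx"]
BREATH_HEADER = ["breath_idx", "onset_ms", "tv_l", "dp_inhale_cmh2o",
                 "dv_inhale_l", "elastance_cmh2o_per_l", "valid"]
TITRATION_HEADER = ["cycle", "centre_cmh2o", "setting_cmh2o", "elastance_est",
                    "argmin", "converged"]

_T_FMT = "%.3f"
_P_FMT = "%.4f"
_V_FMT = "%.4f"
_Q_FMT = "%.2f"
_E_FMT = "%.4f"


def read_raw_stream(path: str | Path) -> FrameStream:
    """Read a raw-dialect CSV into a :class:`FrameStream`.

    Timestamps must be strictly increasing on the wrapping 32-bit clock
    with at most one wrap, which is unwrapped into monotone milliseconds.

    Raises
    ------
    ValueError
        On a header mismatch, a malformed row (reported with its line
        number), or timestamps implying more than one clock wrap.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != RAW_HEADER:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match the raw dialect "
            f"{RAW_HEADER}"
        )
    cols = {}
    for name in RAW_HEADER:
        try:
            cols[name] = df[name].astype(float).to_numpy()
        except ValueError as err:
            bad = df.index[pd.to_numeric(df[name], errors="coerce").isna()][0]
            raise ValueError(
                f"{path}, line {bad + 2}: malformed value {df[name].iloc[bad]!r} "
                f"in column {name}"
            ) from err
    t = cols["t_ms"]
    if np.any(t < 0) or np.any(t >= CLOCK_WRAP_MS):
        raise ValueError(f"{path}: timestamps outside the 32-bit clock range")
    drops = np.flatnonzero(np.diff(t) <= 0)
    if len(drops) > 1:
        raise ValueError(
            f"{path}: timestamps imply more than one clock wrap "
            f"(non-increasing at {len(drops)} positions)"
        )
    if len(drops) == 1:
        i = drops[0] + 1
        t = t.copy()
        t[i:] += CLOCK_WRAP_MS
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{path}: timestamps not monotone even after one unwrap")
    return FrameStream(t, cols["p_gauge_cmh2o"], cols["dp_in_cmh2o"], cols["dp_ex_cmh2o"])


def write_raw_stream(stream: FrameStream, path: str | Path) -> None:
    """Write a :class:`FrameStream` in the raw dialect (deterministic bytes)."""
    df = pd.DataFrame({
        "t_ms": [_T_FMT % v for v in stream.t_ms],
        "p_gauge_cmh2o": [_P_FMT % v for v in stream.p_gauge],
        "dp_in_cmh2o": [_P_FMT % v for v in stream.dp_in],
        "dp_ex_cmh2o": [_P_FMT % v for v in stream.dp_ex],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def write_derived_stream(flow: FlowStream, path: str | Path) -> None:
    """Write a flow/volume stream in the derived dialect."""
    df = pd.DataFrame({
        "t_ms": [_T_FMT % v for v in flow.t_ms],
        "p_gauge_cmh2o": [_P_FMT % v for v in flow.p_gauge],
        "q_lpm": [_Q_FMT % v for v in flow.q_lpm],
        "v_l": [_V_FMT % v for v in flow.v_l],
        "breath_idx": [str(int(v)) for v in flow.breath_idx],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def read_derived_stream(path: str | Path) -> FlowStream:
    """Read a derived-dialect CSV back into a :class:`FlowStream`."""
    df = pd.read_csv(path)
    if list(df.columns) != DERIVED_HEADER:
        raise ValueError(
            f"{path}: header {list(df.columns)} does not match the derived dialect "
            f"{DERIVED_HEADER}"
        )
    return FlowStream(
        df["t_ms"].to_numpy(float), df["q_lpm"].to_numpy(float),
        df["p_gauge_cmh2o"].to_numpy(float), df["v_l"].to_numpy(float),
        df["breath_idx"].to_numpy(int),
    )


def write_breath_table(breaths: list[Breath], path: str | Path) -> None:
    """Write the per-breath table (one row per segmented breath)."""
    df = pd.DataFrame({
        "breath_idx": [b.index for b in breaths],
        "onset_ms": [_T_FMT % b.onset_ms for b in breaths],
        "tv_l": [_V_FMT % b.tidal_volume for b in breaths],
        "dp_inhale_cmh2o": [_P_FMT % b.dp_inhale for b in breaths],
        "dv_inhale_l": [_V_FMT % b.dv_inhale for b in breaths],
        "elastance_cmh2o_per_l": [_E_FMT % b.elastance for b in breaths],
        "valid": [int(b.valid) for b in breaths],
    })
    df.to_csv(path, index=False, lineterminator="\n")


def write_titration_log(result: TitrationResult, path: str | Path) -> None:
    """Write the titration trajectory: one row per (cycle, setting) query."""
    rows = []
    for rec in result.trajectory:
        for setting, e in sorted(rec.elastance_by_setting.items()):
            rows.append({
                "cycle": rec.cycle,
                "centre_cmh2o": _P_FMT % rec.centre,
                "setting_cmh2o": _P_FMT % setting,
                "elastance_est": _E_FMT % e,
                "argmin": int(setting == rec.new_centre),
                "converged": int(result.converged),
            })
    pd.DataFrame(rows, columns=TITRATION_HEADER).to_csv(path, index=False,
                                                        lineterminator="\n")


@dataclass
class RunConfig:
    """Validated run configuration (device geometry, sensors, protocol, seed).

    ``device_faithful`` keeps the sampling rate at or below the device's
    160 Hz BLE cap; disabling it is for numerical experiments only.
    """

    inlet_diameter_mm: float = 22.0
    throat_diameter_mm: float = 7.414
    discharge_coefficient: float = 0.97
    air_density_kg_m3: float = 1.293
    dp_full_scale_cmh2o: float = 50.8
    sample_rate_hz: float = 160.0
    noise_sd_cmh2o: float = 0.05
    quantization_bits: int | None = 12
    device_faithful: bool = True
    seed: int = 0
    query_halfwidth_cmh2o: float = 2.0
    grid_step_cmh2o: float = 1.0
    breaths_per_setting: int = 5
    convergence_k: int = 2
    max_cycles: int = 20
    pressure_bounds_cmh2o: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        if self.device_faithful and self.sample_rate_hz > MAX_SAMPLE_RATE_HZ:
            raise ValueError(
                f"sample_rate_hz={self.sample_rate_hz} exceeds the device's "
                f"{MAX_SAMPLE_RATE_HZ:.0f} Hz cap (BLE transmission limit)"
            )
        # construct the derived objects so their own validation runs
        self.geometry()
        self.gas()
        self.titration_config()

    def geometry(self) -> VenturiGeometry:
        return VenturiGeometry(
            inlet_diameter=self.inlet_diameter_mm / 1000.0,
            throat_diameter=self.throat_diameter_mm / 1000.0,
            discharge_coefficient=self.discharge_coefficient,
        )

    def gas(self) -> GasProperties:
        return GasProperties(density=self.air_density_kg_m3)

    def titration_config(self) -> TitrationConfig:
        return TitrationConfig(
            query_halfwidth=self.query_halfwidth_cmh2o,
            grid_step=self.grid_step_cmh2o,
            breaths_per_setting=self.breaths_per_setting,
            convergence_k=self.convergence_k,
            max_cycles=self.max_cycles,
            pressure_bounds=tuple(self.pressure_bounds_cmh2o),
        )

    def config_hash(self) -> str:
        """Short digest of the resolved config, logged for reproducibility."""
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file, apply keyword overrides, validate strictly.

    Unknown keys are rejected by name.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "pressure_bounds_cmh2o" in data:
        data["pressure_bounds_cmh2o"] = tuple(data["pressure_bounds_cmh2o"])
    cfg = RunConfig(**data)
    logger.info("config loaded", extra={"config_hash": cfg.config_hash()})
    return cfg
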
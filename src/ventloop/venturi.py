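"""Venturi flow model: differential pressure <-> volumetric flow.

A Venturi tube constricts the airway from inlet area ``A1`` to throat area
``A2``; by Bernoulli's principle the inlet-throat pressure drop ``dP``
encodes the volumetric flow

    Q = c_D * A2 * sqrt( (2 dP / rho) / (1 - (A2/A1)^2) )

with ``c_D`` an empirical discharge coefficient (< 1) absorbing viscous
losses.  The model is incompressible with a fixed ``c_D``; no Reynolds or
thermal corrections are applied.

The default geometry matches the device: 22 mm inlet (the standard
respiratory-circuit connector bore) and a throat sized so that the
differential-pressure sensor's +/-50.8 cmH2O full scale corresponds to a
222 L/min flow ceiling at c_D = 0.97 and air density 1.293 kg/m^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import cmh2o_to_pa, pa_to_cmh2o

#: Flow unit conversion: 1 m^3/s = 60_000 L/min.
_LPM_PER_M3S = 60_000.0

DEFAULT_INLET_DIAMETER_M = 0.022
DEFAULT_THROAT_DIAMETER_M = 0.007414
DEFAULT_DISCHARGE_COEFFICIENT = 0.97
DEFAULT_AIR_DENSITY = 1.293  # kg/m^3
DEFAULT_DP_FULL_SCALE_CMH2O = 50.8


def _circle_area(d: float) -> float:
    return math.pi * d * d / 4.0


@dataclass(frozen=True)
class VenturiGeometry:
    """Inlet/throat dimensions and discharge coefficient of one Venturi.

    Parameters
    ----------
    inlet_diameter
        Inlet bore in metres (default 0.022, the standard 22 mm connector).
    throat_diameter
        Throat bore in metres. Must be strictly smaller than the inlet.
    discharge_coefficient
        Dimensionless c_D in (0, 1].
    """

    inlet_diameter: float = DEFAULT_INLET_DIAMETER_M
    throat_diameter: float = DEFAULT_THROAT_DIAMETER_M
    discharge_coefficient: float = DEFAULT_DISCHARGE_COEFFICIENT

    def __post_init__(self) -> None:
        if not (0.0 < self.throat_diameter < self.inlet_diameter):
            raise ValueError(
                "require 0 < throat_diameter < inlet_diameter, got "
                f"throat={self.throat_diameter}, inlet={self.inlet_diameter}"
            )
        if not (0.0 < self.discharge_coefficient <= 1.0):
            raise ValueError(
                f"discharge_coefficient must be in (0, 1], got {self.discharge_coefficient}"
            )

    @property
    def inlet_area(self) -> float:
        """Inlet cross-sectional area A1 in m^2."""
        return _circle_area(self.inlet_diameter)

    @property
    def throat_area(self) -> float:
        """Throat cross-sectional area A2 in m^2."""
        return _circle_area(self.throat_diameter)

    @property
    def area_ratio_sq(self) -> float:
        """(A2/A1)^2, the velocity-of-approach correction term."""
        r = self.throat_area / self.inlet_area
        return r * r


@dataclass(frozen=True)
class GasProperties:
    """Working-gas properties; density defaults to air at 0 degC, 1.293 kg/m^3."""

    density: float = DEFAULT_AIR_DENSITY

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"gas density must be > 0, got {self.density}")


def flow_from_dp(
    dp: float,
    geom: VenturiGeometry | None = None,
    gas: GasProperties | None = None,
) -> float:
    """Volumetric flow (L/min) through a Venturi from its pressure drop (cmH2O).

    ``dp`` must be >= 0: a negative inlet-throat drop means the channel's
    one-way valve is shut, which the sensing layer handles by clamping to
    zero before calling here.

    Flow scales as sqrt(dp), so Q(0) = 0 and Q is strictly increasing.
    """
    geom = geom or VenturiGeometry()
    gas = gas or GasProperties()
    if dp < 0:
        raise ValueError(f"dp must be >= 0 (one-way valve semantics), got {dp}")
    dp_pa = cmh2o_to_pa(dp)
    q_m3s = geom.discharge_coefficient * geom.throat_area * math.sqrt(
        (2.0 * dp_pa / gas.density) / (1.0 - geom.area_ratio_sq)
    )
    return q_m3s * _LPM_PER_M3S


def dp_from_flow(
    q: float,
    geom: VenturiGeometry | None = None,
    gas: GasProperties | None = None,
) -> float:
    """Pressure drop (cmH2O) across a Venturi carrying flow ``q`` (L/min).

    Exact algebraic inverse of :func:`flow_from_dp`.
    """
    geom = geom or VenturiGeometry()
    gas = gas or GasProperties()
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    q_m3s = q / _LPM_PER_M3S
    u = q_m3s / (geom.discharge_coefficient * geom.throat_area)
    dp_pa = 0.5 * gas.density * u * u * (1.0 - geom.area_ratio_sq)
    return pa_to_cmh2o(dp_pa)


def solve_throat_diameter(
    q_target: float,
    dp_target: float,
    inlet_diameter: float = DEFAULT_INLET_DIAMETER_M,
    discharge_coefficient: float = DEFAULT_DISCHARGE_COEFFICIENT,
    gas: GasProperties | None = None,
    rel_tol: float = 1e-12,
    max_iter: int = 50,
) -> float:
    """Throat diameter (m) for which ``dp_target`` cmH2O reads ``q_target`` L/min.

    Design-side inversion of the Venturi equation by fixed-point iteration on

        A2 <- (Q / (c_D sqrt(2 dP / rho))) * sqrt(1 - (A2/A1)^2)

    starting from the zero-approach-velocity solution; the contraction factor
    is (A2/A1)^2 < 1 so a handful of iterations suffice.

    Raises
    ------
    ValueError
        If inputs are non-positive or the required throat would not be
        smaller than the inlet.
    """
    gas = gas or GasProperties()
    if q_target <= 0 or dp_target <= 0 or inlet_diameter <= 0:
        raise ValueError("q_target, dp_target and inlet_diameter must all be > 0")
    a1 = _circle_area(inlet_diameter)
    q_m3s = q_target / _LPM_PER_M3S
    k = q_m3s / (discharge_coefficient * math.sqrt(2.0 * cmh2o_to_pa(dp_target) / gas.density))
    a2 = k  # beta -> 0 limit
    for _ in range(max_iter):
        ratio_sq = (a2 / a1) ** 2
        if ratio_sq >= 1.0:
            raise ValueError(
                "no throat smaller than the inlet achieves the requested flow at this dp"
            )
        a2_next = k * math.sqrt(1.0 - ratio_sq)
        if abs(a2_next - a2) <= rel_tol * a2:
            a2 = a2_next
            break
        a2 = a2_next
    d2 = math.sqrt(4.0 * a2 / math.pi)
    if d2 >= inlet_diameter:
        raise ValueError(
            f"solved throat diameter {d2:.6g} m is not smaller than the inlet "
            f"{inlet_diameter:.6g} m"
        )
    return d2


@dataclass(frozen=True)
class OperatingEnvelope:
    """The device's measurement envelope under a given geometry and gas.

    ``dp_full_scale`` is the differential sensor's full-scale reading
    (default +/-50.8 cmH2O); ``q_max`` is the corresponding flow ceiling,
    derived at construction and kept consistent with the active geometry.
    """

    dp_full_scale: float = DEFAULT_DP_FULL_SCALE_CMH2O
    geom: VenturiGeometry = field(default_factory=VenturiGeometry)
    gas: GasProperties = field(default_factory=GasProperties)

    def __post_init__(self) -> None:
        if not self.dp_full_scale > 0:
            raise ValueError("dp_full_scale must be > 0")

    @property
    def q_max(self) -> float:
        """Flow ceiling in L/min: flow_from_dp at the sensor full scale."""
        return flow_from_dp(self.dp_full_scale, self.geom, self.gas)
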
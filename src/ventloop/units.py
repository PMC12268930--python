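"""Physical-unit conventions and the device's 32-bit millisecond clock.

The package speaks cmH2O, L, L/min and cmH2O/L at its API surface — the
units clinicians and ventilators use — and converts to SI (Pa, m3, m3/s)
only inside physical formulas.  The conversion constant is the conventional
one, 98.0665 Pa per cmH2O (standard gravity acting on a 1 cm column of
water at 4 degC).

The device firmware stores runtime as an unsigned 32-bit millisecond
counter, which wraps after 2^32 ms (about 49.7 days) and therefore bounds
continuous operation.  Elapsed-time arithmetic here is correct across a
single wrap; stream readers reject streams spanning more than one wrap.
"""

from __future__ import annotations

import math

PA_PER_CMH2O: float = 98.0665
"""Pa per cmH2O (conventional centimetre of water)."""

CLOCK_WRAP_MS: int = 2**32
"""Wrap period of the device's unsigned 32-bit millisecond counter."""

MS_PER_DAY: int = 86_400_000


def cmh2o_to_pa(p: float) -> float:
    """Convert a pressure from cmH2O to Pa.

    Parameters
    ----------
    p
        Pressure in cmH2O. Must be finite.
    """
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    return p * PA_PER_CMH2O


def pa_to_cmh2o(p: float) -> float:
    """Convert a pressure from Pa to cmH2O (inverse of :func:`cmh2o_to_pa`)."""
    if not math.isfinite(p):
        raise ValueError(f"pressure must be finite, got {p!r}")
    return p / PA_PER_CMH2O


def elapsed_ms(t0: float, t1: float, wrap: int = CLOCK_WRAP_MS) -> float:
    """Elapsed milliseconds from tick ``t0`` to tick ``t1`` on a wrapping clock.

    Returns ``(t1 - t0) mod wrap``, which is the true elapsed time provided
    the interval spans at most one counter wrap.

    Both ticks must lie in ``[0, wrap)``.
    """
    if not (0 <= t0 < wrap):
        raise ValueError(f"tick t0={t0!r} outside [0, {wrap})")
    if not (0 <= t1 < wrap):
        raise ValueError(f"tick t1={t1!r} outside [0, {wrap})")
    return (t1 - t0) % wrap


def max_runtime_days(counter_bits: int = 32) -> int:
    """Whole days of continuous operation a ``counter_bits``-bit ms counter allows.

    ``floor(2**counter_bits / 86_400_000)`` — 49 days for the device's
    32-bit counter.
    """
    if counter_bits < 1:
        raise ValueError("counter_bits must be >= 1")
    return (1 << counter_bits) // MS_PER_DAY
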
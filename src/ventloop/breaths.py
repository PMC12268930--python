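"""Breath segmentation, volume integration and per-breath elastance.

Each breath's elastance is read off its pressure-volume loop: the change
in airway pressure over the inhalation limb divided by the change in
volume over the same limb,

    E = dP_inhale / dV_inhale      [cmH2O/L]

which is the reciprocal gradient of the loop's inhalation portion.  At
zero-flow endpoints (onset and an end-inspiratory plateau) the resistive
pressure drop vanishes, so the endpoint quotient equals the compartment
elastance; with flow at the endpoints it picks up a resistive bias, which
the least-squares variant (:func:`elastance_least_squares`) trades against
noise averaging.

Volume is the trapezoidal time-integral of the signed flow, reset to zero
at every breath onset so integrator drift cannot accumulate across breaths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensing import FlowStream

DEFAULT_ONSET_THRESHOLD_LPM = 2.0
DEFAULT_DEBOUNCE_MS = 100.0
MIN_BREATH_DURATION_S = 0.5
MIN_TIDAL_VOLUME_L = 0.05


@dataclass
class Breath:
    """One segmented breath and its elastance estimate.

    ``dp_inhale``/``dv_inhale`` are taken between inhalation onset and end
    of inhalation; ``elastance`` is exactly their quotient (NaN when the
    breath is invalid).  ``p_inhale``/``v_inhale`` hold the inhalation-limb
    PV-loop arrays.
    """

    index: int
    onset_ms: float
    offset_ms: float
    p_inhale: np.ndarray
    v_inhale: np.ndarray
    tidal_volume: float
    dp_inhale: float
    dv_inhale: float
    elastance: float
    valid: bool
    invalid_reason: str | None = None

    @property
    def duration_s(self) -> float:
        return (self.offset_ms - self.onset_ms) / 1000.0


def segment_breaths(flow: FlowStream,
                    onset_threshold: float = DEFAULT_ONSET_THRESHOLD_LPM,
                    debounce_ms: float = DEFAULT_DEBOUNCE_MS) -> list[int]:
    """Indices of breath onsets in a signed-flow stream.

    An onset is a rising crossing of ``+onset_threshold`` L/min that stays
    above threshold for at least ``debounce_ms`` (suppresses sub-threshold
    noise).  Breaths span onset to next onset.  Returns an empty list when
    nothing crosses.
    """
    q = flow.q_lpm
    t = flow.t_ms
    if len(q) == 0:
        return []
    above = q >= onset_threshold
    rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
    onsets: list[int] = []
    for i in rising:
        # require the signal to hold above threshold through the debounce window
        j = i
        while j + 1 < len(q) and above[j + 1]:
            j += 1
        if t[j] - t[i] >= debounce_ms:
            onsets.append(int(i))
    return onsets


def integrate_volume(flow: FlowStream, onsets: list[int]) -> FlowStream:
    """Fill ``flow.v_l`` by trapezoidal integration, resetting at each onset.

    Volume before the first onset integrates from the stream start (still
    drift-corrected at the first onset).  Also stamps ``breath_idx`` (-1
    before the first onset).  Timestamps must be monotone.
    """
    t_s = flow.t_ms / 1000.0
    if len(t_s) > 1 and np.any(np.diff(t_s) <= 0):
        raise ValueError("non-monotone timestamps")
    q_lps = flow.q_lpm / 60.0
    # cumulative trapezoid over the whole stream, then re-zero per breath
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (q_lps[1:] + q_lps[:-1]) * np.diff(t_s))])
    v = cum.copy()
    idx = np.full(len(v), -1, dtype=int)
    for b, i0 in enumerate(onsets):
        i1 = onsets[b + 1] if b + 1 < len(onsets) else len(v)
        v[i0:i1] = cum[i0:i1] - cum[i0]
        idx[i0:i1] = b
    flow.v_l = v
    flow.breath_idx = idx
    return flow


def _end_of_inhalation(q: np.ndarray, i0: int, i1: int, threshold: float) -> int:
    """Last sample of the inhalation limb within [i0, i1).

    The limb runs through any end-inspiratory plateau and ends at the last
    sample before flow turns expiratory (falls through ``-threshold``).
    Ending at the plateau rather than at the ``+threshold`` downcrossing
    keeps the endpoint flow near zero, so the resistive pressure drop does
    not contaminate the elastance quotient.  If the breath never develops
    expiratory flow, the limb ends at the ``+threshold`` downcrossing
    instead (or the breath's last sample).
    """
    seg = q[i0:i1]
    expir = np.flatnonzero(seg <= -threshold)
    expir = expir[expir > 0]
    if len(expir):
        return i0 + int(expir[0]) - 1
    below = np.flatnonzero(seg < threshold)
    below = below[below > 0]
    if len(below):
        return i0 + int(below[0]) - 1
    return i1 - 1


def elastance_least_squares(p: np.ndarray, v: np.ndarray) -> float:
    """Secondary estimator: reciprocal slope of V on P over the inhalation limb.

    Fits V = a + m*P by least squares and returns 1/m.  Averages over the
    whole limb (noise-robust) but inherits a resistive bias wherever flow
    is nonzero along the limb; the endpoint quotient stays the primary
    estimator.
    """
    if len(p) < 2:
        return float("nan")
    m = np.polyfit(p, v, 1)[0]
    if m <= 0:
        return float("nan")
    return 1.0 / m


def extract_breaths(flow: FlowStream,
                    onsets: list[int] | None = None,
                    onset_threshold: float = DEFAULT_ONSET_THRESHOLD_LPM,
                    debounce_ms: float = DEFAULT_DEBOUNCE_MS,
                    min_duration_s: float = MIN_BREATH_DURATION_S,
                    min_tidal_volume_l: float = MIN_TIDAL_VOLUME_L) -> list[Breath]:
    """Segment, integrate and estimate elastance for every breath in a stream.

    Breaths shorter than ``min_duration_s`` or with tidal volume below
    ``min_tidal_volume_l`` are flagged invalid (artefact filter); breaths
    with non-positive inhaled volume get no estimate.
    """
    if onsets is None:
        onsets = segment_breaths(flow, onset_threshold, debounce_ms)
    integrate_volume(flow, onsets)
    q, p, v, t = flow.q_lpm, flow.p_gauge, flow.v_l, flow.t_ms
    breaths: list[Breath] = []
    for b, i0 in enumerate(onsets):
        i1 = onsets[b + 1] if b + 1 < len(onsets) else len(q)
        ie = _end_of_inhalation(q, i0, i1, onset_threshold)
        # pressure start point: the sample just before the onset crossing,
        # where flow is still below threshold — at the crossing sample itself
        # the resistive drop R*q is already in the gauge reading and would
        # bias the quotient low
        is_ = max(i0 - 1, 0)
        dp = float(p[ie] - p[is_])
        dv = float(v[ie] - v[i0])
        tv = float(np.max(v[i0:i1]))
        dur_s = (t[i1 - 1] - t[i0]) / 1000.0
        reason = None
        if dv <= 0:
            reason = "non-positive inhaled volume"
        elif dur_s < min_duration_s:
            reason = f"duration {dur_s:.2f}s below {min_duration_s}s"
        elif tv < min_tidal_volume_l:
            reason = f"tidal volume {tv:.3f}L below {min_tidal_volume_l}L"
        e = dp / dv if reason is None else float("nan")
        breaths.append(Breath(
            index=b,
            onset_ms=float(t[i0]),
            offset_ms=float(t[i1 - 1]),
            p_inhale=p[i0:ie + 1].copy(),
            v_inhale=v[i0:ie + 1].copy(),
            tidal_volume=tv,
            dp_inhale=dp,
            dv_inhale=dv,
            elastance=e,
            valid=reason is None,
            invalid_reason=reason,
        ))
    return breaths


def elastance_of_breath(breath: Breath) -> float:
    """Primary elastance estimate of a breath: dP_inhale / dV_inhale.

    Raises
    ------
    ValueError
        If the breath was flagged invalid (e.g. non-positive dV_inhale).
    """
    if not breath.valid:
        raise ValueError(f"invalid breath (index {breath.index}): {breath.invalid_reason}")
    return breath.dp_inhale / breath.dv_inhale
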
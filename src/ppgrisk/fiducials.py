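"""Landmark detection on single PPG beats and their derivatives.

Each beat (onset-to-onset window) is amplitude-normalized to [0, 1] and
differentiated twice.  On the PPG itself the landmarks are the systolic
notch N (the onset, t = 0), the systolic peak P and the diastolic peak D;
on the second derivative (APG, the acceleration of blood flow) they are the
early systolic waves A (first local maximum) and B (first local minimum)
and the diastolic waves E (local maximum announcing the reflected wave) and
F (the following local minimum, where the PPG approximately reaches the
diastolic peak).

D is primarily located as a positive-to-negative zero crossing of the first
derivative (VPG) after the systolic peak; many beats have no conspicuous
diastolic peak, in which case the projection of F onto the PPG is used as
the alternative for D (``d_from_fallback``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "DerivativeSet",
    "BeatFiducials",
    "DegenerateBeatError",
    "BeatRejected",
    "normalize_beat",
    "compute_derivatives",
    "annotate_beat",
]

# search-window defaults; the physiology only loosely constrains these, so
# they are deliberately configurable
P_SEARCH_FRACTION = 0.6   # P searched within the first 60 % of the beat
D_GUARD_MS = 80.0         # guard band around P / beat end for the VPG crossing
SMOOTH_MS = 40.0          # moving-average width before central differences


class DegenerateBeatError(ValueError):
    """Beat has no amplitude range (constant)."""


class BeatRejected(ValueError):
    """No systolic peak could be located; beat unusable."""


@dataclass
class DerivativeSet:
    """A normalized beat with its first (VPG) and second (APG) derivatives."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    sampling_rate: float


@dataclass
class BeatFiducials:
    """Landmark times (ms from beat onset) and amplitudes for one beat.

    ``t_D``/``y_D`` are ``None`` when no diastolic peak could be assigned at
    all; ``d_from_fallback`` records whether D came from the F-projection
    alternative rather than the VPG zero-crossing rule.
    """

    t_N: float
    t_P: float
    t_D: float | None
    t_A: float | None
    t_B: float | None
    t_E: float | None
    t_F: float | None
    t_next_N: float
    y_N: float
    y_P: float
    y_D: float | None
    y_A: float | None
    y_B: float | None
    y_E: float | None
    d_from_fallback: bool


def normalize_beat(beat: np.ndarray) -> np.ndarray:
    """Affine-map the beat amplitude to the range [0, 1]."""
    beat = np.asarray(beat, dtype=float)
    lo, hi = beat.min(), beat.max()
    if hi == lo:
        raise DegenerateBeatError("constant beat cannot be normalized")
    return (beat - lo) / (hi - lo)


def compute_derivatives(beat: np.ndarray, sampling_rate: float,
                        smooth_points: int | None = None) -> DerivativeSet:
    """First and second time derivatives of a (normalized) beat.

    Central differences after moving-average smoothing over roughly 40 ms
    (override with ``smooth_points``); raw double differencing amplifies
    noise quadratically in the APG and makes the zero-crossing landmark
    rules fire on noise rather than on the pulse.  Units are amplitude per
    second and per second squared.
    """
    beat = np.asarray(beat, dtype=float)
    if beat.size < 5:
        raise ValueError("beat too short to differentiate")
    if smooth_points is None:
        smooth_points = max(5, int(round(SMOOTH_MS / 1000.0 * sampling_rate)) | 1)
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        padded = np.pad(beat, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")[: beat.size]
    else:
        smoothed = beat
    dt = 1.0 / sampling_rate
    vpg = np.gradient(smoothed, dt)
    apg = np.gradient(vpg, dt)
    # landmarks are read off the smoothed waveform so that the zero-crossing
    # and local-maximum rules see the pulse, not the residual noise
    return DerivativeSet(ppg=smoothed, vpg=vpg, apg=apg,
                         sampling_rate=sampling_rate)


def _local_maxima(x: np.ndarray, order: int = 2) -> np.ndarray:
    return sps.argrelextrema(x, np.greater_equal, order=order)[0]


def _local_minima(x: np.ndarray, order: int = 2) -> np.ndarray:
    return sps.argrelextrema(x, np.less_equal, order=order)[0]


def annotate_beat(
    derivs: DerivativeSet,
    p_search_fraction: float = P_SEARCH_FRACTION,
    d_guard_ms: float = D_GUARD_MS,
) -> BeatFiducials:
    """Locate N, P, D on the PPG and A, B, E, F on the APG of one beat.

    Rules (all times relative to the beat onset, which is t_N = 0):

    * P  — maximum of the PPG within the first ``p_search_fraction`` of the beat.
    * A  — first APG local maximum after the onset; B — first APG local
      minimum after A.
    * E  — largest APG local maximum in (t_P, t_next_N); F — first APG local
      minimum after E.
    * D  — VPG positive-to-negative zero crossing in
      (t_P + guard, t_next_N - guard) whose PPG value is a local maximum;
      if none qualifies, D falls back to the PPG value at t_F.
    """
    ppg, vpg, apg = derivs.ppg, derivs.vpg, derivs.apg
    fs = derivs.sampling_rate
    n = ppg.size
    ms = 1000.0 / fs  # ms per sample
    guard = max(1, int(round(d_guard_ms / ms)))

    p_hi = max(2, int(round(n * p_search_fraction)))
    i_p = 1 + int(np.argmax(ppg[1:p_hi]))
    if ppg[i_p] <= ppg[0]:
        raise BeatRejected("no systolic peak above onset amplitude")

    # extrema windows in time units so detection is noise-tolerant at any fs
    w_apg = max(2, int(round(0.010 * fs)))   # 10 ms for the fast APG waves
    w_ppg = max(2, int(round(0.020 * fs)))   # 20 ms for PPG peaks

    # A, B: first APG max/min on the systolic upstroke
    apg_max = _local_maxima(apg, w_apg)
    apg_min = _local_minima(apg, w_apg)
    a_candidates = apg_max[(apg_max > 0) & (apg_max < i_p)]
    i_a = int(a_candidates[0]) if a_candidates.size else None
    i_b = None
    if i_a is not None:
        b_candidates = apg_min[apg_min > i_a]
        i_b = int(b_candidates[0]) if b_candidates.size else None

    # E, F: diastolic acceleration landmarks after the systolic peak.  The
    # final guard band is excluded: near the window end the curvature of the
    # next beat's upstroke would otherwise masquerade as E.
    e_candidates = apg_max[(apg_max > i_p) & (apg_max < n - guard)]
    i_e = int(e_candidates[np.argmax(apg[e_candidates])]) if e_candidates.size else None
    i_f = None
    if i_e is not None:
        f_candidates = apg_min[(apg_min > i_e) & (apg_min < n - guard)]
        if f_candidates.size:
            i_f = int(f_candidates[0])
        elif n - guard > i_e + 2:
            # monotone APG decay: take the flattest point before the guard
            i_f = i_e + 1 + int(np.argmin(apg[i_e + 1: n - guard]))

    # D primary path: VPG + -> - zero crossing sitting on a PPG local
    # maximum.  The crossing qualifies only if the PPG maximum of its
    # neighborhood is interior (a decaying tail has its maximum at the
    # window edge), which rejects noise-induced crossings.
    i_d = None
    fallback = False
    lo, hi = i_p + guard, n - guard
    if hi > lo:
        seg = vpg[lo:hi]
        crossings = np.flatnonzero((seg[:-1] > 0) & (seg[1:] <= 0)) + lo
        for c in crossings:
            a = max(0, c - w_ppg)
            b = min(n, c + w_ppg + 1)
            j = a + int(np.argmax(ppg[a:b]))
            # a genuine diastolic peak follows the dicrotic notch: require a
            # real dip between the systolic peak and the candidate, which
            # rejects ripples riding on a flat systolic shoulder
            dip = ppg[j] - float(np.min(ppg[i_p:j + 1])) if j > i_p else 0.0
            if a < j < b - 1 and dip >= 0.015 * (ppg.max() - ppg.min()):
                i_d = j
                break
    if i_d is None and i_f is not None:
        i_d = i_f
        fallback = True

    t = lambda i: None if i is None else i * ms
    y_ppg = lambda i: None if i is None else float(ppg[i])
    y_apg = lambda i: None if i is None else float(apg[i])

    return BeatFiducials(
        t_N=0.0, t_P=i_p * ms, t_D=t(i_d),
        t_A=t(i_a), t_B=t(i_b), t_E=t(i_e), t_F=t(i_f),
        t_next_N=n * ms,
        y_N=float(ppg[0]), y_P=float(ppg[i_p]), y_D=y_ppg(i_d),
        y_A=y_apg(i_a), y_B=y_apg(i_b), y_E=y_apg(i_e),
        d_from_fallback=fallback,
    )
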
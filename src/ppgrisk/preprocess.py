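"""Segment selection, band-pass filtering, pulse-onset detection and quality gating.

The processing chain mirrors a standard home-monitoring PPG protocol: each
60 s record carries three 20 s luminous-intensity segments and only the
medium-intensity segment is analysed.  That segment is band-pass filtered
(Butterworth, 0.2-20 Hz, zero phase), pulse onsets (the systolic notch N,
i.e. the foot of each beat) are detected with a slope-sum-function detector,
and a template-correlation signal-quality index gates the record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import PPGRecord

__all__ = [
    "CleanSignal",
    "OnsetTrain",
    "QualityVerdict",
    "SelectionError",
    "select_medium_segment",
    "bandpass_filter",
    "detect_onsets",
    "segment_beats",
    "assess_quality",
]

LOW_CUTOFF_HZ = 0.2
HIGH_CUTOFF_HZ = 20.0
FILTER_ORDER = 4
MIN_SIGNAL_S = 3.0

# slope-sum-function onset detector defaults
SSF_WINDOW_S = 0.128
SSF_THRESHOLD_FRAC = 0.6
SSF_REFRACTORY_S = 0.300

SQI_THRESHOLD = 0.8
HR_RANGE_BPM = (30.0, 180.0)
CLIP_FRACTION = 0.01


class SelectionError(ValueError):
    """No usable medium-intensity segment."""


@dataclass
class CleanSignal:
    """A band-pass filtered, DC-free signal ready for feature extraction."""

    samples: np.ndarray
    sampling_rate: float
    source_record_id: str = ""
    segment_origin: str = "medium"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class OnsetTrain:
    """Strictly increasing sample indices of the systolic notch of each beat."""

    onset_indices: np.ndarray

    def __post_init__(self) -> None:
        self.onset_indices = np.asarray(self.onset_indices, dtype=int)
        if self.onset_indices.size > 1 and np.any(np.diff(self.onset_indices) <= 0):
            raise ValueError("onset indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.onset_indices.size)


@dataclass
class QualityVerdict:
    sqi: float
    passed: bool
    reasons: list[str] = field(default_factory=list)


def select_medium_segment(record: PPGRecord) -> np.ndarray:
    """Return the raw samples of the record's medium-intensity span.

    Selection is by segment label, not position.  If the record carries no
    segment map at all, the middle third of the record is used as a
    documented fallback.
    """
    spans = [(a, b) for a, b, lab in record.segment_map if lab == "medium"]
    if not record.segment_map:
        n = record.samples.size
        return record.samples[n // 3: 2 * (n // 3)]
    if not spans:
        raise SelectionError("record has no medium-intensity segment")
    if len(spans) > 1:
        raise SelectionError("record has multiple medium-intensity segments")
    a, b = spans[0]
    return record.samples[a:b]


def bandpass_filter(
    samples: np.ndarray,
    sampling_rate: float,
    low_hz: float = LOW_CUTOFF_HZ,
    high_hz: float = HIGH_CUTOFF_HZ,
    order: int = FILTER_ORDER,
    record_id: str = "",
) -> CleanSignal:
    """Zero-phase Butterworth band-pass (default 0.2-20 Hz, order 4).

    Applied forward-backward (``sosfiltfilt``) so fiducial timing carries no
    group delay; phase distortion would bias every interval feature downstream.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < MIN_SIGNAL_S * sampling_rate:
        raise ValueError(
            f"need at least {MIN_SIGNAL_S:g} s of signal, got "
            f"{samples.size / sampling_rate:.2f} s"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass",
                     fs=sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, samples)
    return CleanSignal(filtered, sampling_rate, source_record_id=record_id)


def _slope_sum_function(x: np.ndarray, window: int) -> np.ndarray:
    """Windowed sum of positive first differences (upstroke energy)."""
    dx = np.diff(x, prepend=x[0])
    du = np.where(dx > 0, dx, 0.0)
    kernel = np.ones(window)
    return np.convolve(du, kernel)[: x.size]


def detect_onsets(
    signal: CleanSignal,
    window_s: float = SSF_WINDOW_S,
    threshold_frac: float = SSF_THRESHOLD_FRAC,
    refractory_s: float = SSF_REFRACTORY_S,
) -> OnsetTrain:
    """Detect the systolic notch (pulse foot) of every beat.

    Slope-sum-function detector: the filtered PPG's positive slopes are summed
    over a 128 ms window; an adaptive threshold at 60 % of a decaying running
    SSF maximum triggers on each systolic upstroke, with a 300 ms refractory
    period; the onset is then placed at the local minimum of the PPG preceding
    the upstroke.
    """
    x = signal.samples
    fs = signal.sampling_rate
    if x.size < MIN_SIGNAL_S * fs:
        raise ValueError("signal shorter than 3 s")
    if not np.any(x != x[0]):
        return OnsetTrain(np.empty(0, dtype=int))
    win = max(2, int(round(window_s * fs)))
    refractory = int(round(refractory_s * fs))
    ssf = _slope_sum_function(x, win)

    # adaptive threshold: fraction of the SSF maximum over the trailing 3 s,
    # which tracks slow amplitude drift without chasing noise spikes
    from scipy.ndimage import maximum_filter1d
    trail = int(round(3.0 * fs))
    run_max = maximum_filter1d(ssf, size=trail, mode="nearest",
                               origin=(trail - 1) // 2)
    # early samples see too little history; backfill with the 2 s maximum
    head = int(2 * fs)
    if ssf.size > head:
        run_max[:head] = np.maximum(run_max[:head], np.max(ssf[:head]))

    thresh = threshold_frac * run_max
    above = ssf > np.maximum(thresh, 1e-12)
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1

    onsets: list[int] = []
    last = -refractory - 1
    for c in crossings:
        if c - last < refractory:
            continue
        # onset = local minimum of the PPG in the window preceding the upstroke
        lo = max(0, c - win)
        seg = x[lo: c + 1]
        if seg.size == 0:
            continue
        onset = lo + int(np.argmin(seg))
        # advance to the takeoff edge of the valley: across a flat or gently
        # descending foot the onset is the last sample before the upstroke
        limit = min(x.size - 2, onset + win)
        while onset < limit and x[onset + 1] <= x[onset]:
            onset += 1
        if onsets and onset - onsets[-1] < refractory:
            continue
        onsets.append(onset)
        last = c

    idx = np.asarray(onsets, dtype=int)
    # prune false triggers on the diastolic upstroke: a true systolic onset
    # is followed by a rise close to the full pulse amplitude, a diastolic
    # one only by the (much smaller) reflected-wave rise
    if idx.size >= 3:
        horizon = int(round(0.30 * fs))
        amps = np.array([x[i: i + horizon].max() - x[i] for i in idx])
        ref = np.quantile(amps, 0.9)
        idx = idx[amps >= 0.45 * ref]
        # backstop: drop the weaker onset of any implausibly short interval
        while idx.size >= 3:
            intervals = np.diff(idx)
            med = np.median(intervals)
            short = np.flatnonzero(intervals < 0.55 * med)
            if short.size == 0:
                break
            k = int(short[0])
            a = np.array([x[i: i + horizon].max() - x[i] for i in idx[k:k + 2]])
            idx = np.delete(idx, k if a[0] < a[1] else k + 1)
    return OnsetTrain(idx)


def segment_beats(signal: CleanSignal, onsets: OnsetTrain) -> list[np.ndarray]:
    """Split the signal into per-beat windows ``[onset_k, onset_{k+1})``.

    The k-th beat runs from onset k to (but not including) onset k+1, so the
    beats partition the signal between the first and last onset.
    """
    idx = onsets.onset_indices
    if idx.size < 2:
        raise ValueError("need at least 2 onsets to segment beats")
    return [signal.samples[a:b] for a, b in zip(idx[:-1], idx[1:])]


def assess_quality(
    signal: CleanSignal,
    onsets: OnsetTrain,
    sqi_threshold: float = SQI_THRESHOLD,
    min_beats: int = 5,
) -> QualityVerdict:
    """Template-correlation signal-quality index with hard failure gates.

    The SQI is the mean pairwise Pearson correlation of all beats resampled
    to a common length (clipped below at 0).  Hard failures: fewer than
    ``min_beats`` beats, >=1 % of samples clipped at an amplitude rail, or a
    median heart rate outside 30-180 bpm.
    """
    reasons: list[str] = []
    x = signal.samples
    fs = signal.sampling_rate

    ptp = float(np.ptp(x))
    if ptp == 0:
        reasons.append("flatline")
    else:
        tol = 1e-9 * ptp
        frac_rail = max(np.mean(x >= x.max() - tol), np.mean(x <= x.min() + tol))
        if frac_rail >= CLIP_FRACTION:
            reasons.append("clipping")

    idx = onsets.onset_indices
    if idx.size < min_beats + 1:
        reasons.append("too_few_beats")
        return QualityVerdict(sqi=0.0, passed=False, reasons=reasons)

    intervals = np.diff(idx) / fs
    hr = 60.0 / np.median(intervals)
    if not (HR_RANGE_BPM[0] <= hr <= HR_RANGE_BPM[1]):
        reasons.append("implausible_rate")

    beats = segment_beats(signal, onsets)
    L = int(np.median([b.size for b in beats]))
    resampled = np.vstack([
        np.interp(np.linspace(0, 1, L), np.linspace(0, 1, b.size), b)
        for b in beats if b.size >= 2
    ])
    c = np.corrcoef(resampled)
    n = c.shape[0]
    sqi = float(np.clip((c.sum() - n) / (n * (n - 1)), 0.0, 1.0)) if n > 1 else 0.0

    passed = sqi >= sqi_threshold and not reasons
    return QualityVerdict(sqi=sqi, passed=passed, reasons=reasons)
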
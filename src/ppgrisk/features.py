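"""The 30-dimensional PPG feature vector.

Fourteen time-domain features are read off the per-beat fiducials (intervals,
amplitude ratios, slopes, areas, pulse widths), five frequency-domain
features are normalized harmonic powers from a Welch power-spectral-density
estimate, and eleven energy features come from an 8-level wavelet packet
decomposition (sym6): the normalized energies of the ten lowest 0.977 Hz
sub-bands (0-9.77 Hz) plus the total energy in dB.

Time-domain features are aggregated across the beats of a record by the
median (robust to residual artifact beats); the spectral and wavelet
features are computed once on the full 20 s signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pywt

from .fiducials import (BeatFiducials, BeatRejected, DegenerateBeatError,
                        annotate_beat, compute_derivatives, normalize_beat)
from .io import SubjectProfile
from .preprocess import CleanSignal, OnsetTrain, segment_beats

__all__ = [
    "FEATURE_NAMES",
    "TimeFeatures",
    "PSDEstimate",
    "HarmonicFeatures",
    "WPDEnergies",
    "FeatureVector",
    "time_features",
    "pulse_widths",
    "welch_psd",
    "harmonic_features",
    "wpd_energies",
    "record_feature_vector",
]

TIME_FEATURE_NAMES = ("Tp", "Td", "HR", "RI", "SI", "T_RD", "Rslop", "Dslop",
                      "Rarea", "VDab", "VDae", "W25", "W50", "W75")
HARMONIC_FEATURE_NAMES = ("H1", "H2", "H3", "H4", "H5")
WPD_FEATURE_NAMES = tuple(f"E{i}" for i in range(1, 11)) + ("Eall",)
FEATURE_NAMES = TIME_FEATURE_NAMES + HARMONIC_FEATURE_NAMES + WPD_FEATURE_NAMES

WELCH_SEGMENT = 4096      # M: samples per segment
WELCH_STRIDE = 1024       # S: stride between segment starts
WELCH_WINDOW = "hann"
#: Signals are rescaled to this RMS (nominal fingertip-PPG ADC amplitude)
#: before PSD estimation.  The dB-ratio harmonic features H1..H5 depend on
#: the absolute dB reference; anchoring it at a device-like amplitude puts
#: the ratios of ordinary pulse waveforms in the physiological range
#: (H1 ~ 0.85 falling to H5 ~ 0.45) rather than compressing them.
WELCH_REFERENCE_RMS = 12.0
HARMONIC_TOL_HZ = 0.3     # harmonic peak must lie within this of k*f0
WPD_WAVELET = "sym6"
WPD_LEVEL = 8


@dataclass
class TimeFeatures:
    """The 14 time-domain features of one beat (times ms, HR bpm, SI m/s)."""

    Tp: float
    Td: float | None
    HR: float
    RI: float | None
    SI: float | None
    T_RD: float
    Rslop: float
    Dslop: float
    Rarea: float | None
    VDab: float | None
    VDae: float | None
    W25: float | None
    W50: float | None
    W75: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class PSDEstimate:
    """Welch PSD in dB with the segmenting bookkeeping that produced it."""

    frequencies: np.ndarray
    psd_db: np.ndarray
    segment_length: int
    stride: int
    window: str
    segment_count: int


@dataclass
class HarmonicFeatures:
    fundamental_hz: float
    O: np.ndarray                  # dB power at harmonics 1..6 (NaN if absent)
    H: np.ndarray                  # H1..H5 = O[k]/O[0], k = 1..5


@dataclass
class WPDEnergies:
    level: int
    node_energies: np.ndarray      # 2**level entries, frequency-ordered
    band_width_hz: float
    Eall_linear: float
    Eall_db: float
    E: np.ndarray                  # normalized energies of the 10 lowest bands


@dataclass
class FeatureVector:
    """The 30 named features for one record, with per-feature missing flags."""

    values: dict[str, float] = field(default_factory=dict)
    missing: set[str] = field(default_factory=set)
    subject_id: str = ""
    record_id: str = ""
    event_label: int = 0

    def __post_init__(self) -> None:
        assert set(self.values) | self.missing >= set(FEATURE_NAMES) or not self.values

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# time domain

def pulse_widths(beat: np.ndarray, fiducials: BeatFiducials,
                 fraction: float, sampling_rate: float) -> float | None:
    """Pulse width (ms) at ``fraction`` of the systolic-peak height.

    Width = time between the last upward crossing of ``fraction * y_P``
    before the systolic peak and the first downward crossing after it, with
    linear interpolation between samples.  Returns ``None`` if the level is
    never crossed on either side.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    i_p = int(round(fiducials.t_P * sampling_rate / 1000.0))
    level = fraction * fiducials.y_P
    ms = 1000.0 / sampling_rate

    before = beat[: i_p + 1]
    ups = np.flatnonzero((before[:-1] < level) & (before[1:] >= level))
    after = beat[i_p:]
    downs = np.flatnonzero((after[:-1] >= level) & (after[1:] < level))
    if ups.size == 0 or downs.size == 0:
        return None
    i0 = ups[-1]
    t0 = i0 + (level - before[i0]) / (before[i0 + 1] - before[i0])
    j0 = downs[0]
    t1 = i_p + j0 + (level - after[j0]) / (after[j0 + 1] - after[j0])
    return float((t1 - t0) * ms)


def time_features(fiducials: BeatFiducials, beat: np.ndarray,
                  sampling_rate: float,
                  subject_height_cm: float | None) -> TimeFeatures:
    """Compute the 14 time-domain features of one normalized beat.

    ``beat`` must be the amplitude-normalized beat the fiducials were
    annotated on.  SI uses the subject height in metres over the
    peak-to-diastolic-peak transit time in seconds.
    """
    f = fiducials
    Tp = f.t_P - f.t_N
    beat_ms = f.t_next_N - f.t_N
    HR = 60000.0 / beat_ms
    T_RD = Tp / (f.t_next_N - f.t_P)
    Rslop = (f.y_P - f.y_N) / Tp
    Dslop = (f.y_P - f.y_N) / (f.t_next_N - f.t_P)

    Td = RI = SI = Rarea = None
    if f.t_D is not None:
        Td = f.t_D - f.t_N
        RI = f.y_D / f.y_P if f.y_P else None
        transit_s = (f.t_D - f.t_P) / 1000.0
        if subject_height_cm is not None and transit_s > 0:
            SI = (subject_height_cm / 100.0) / transit_s

    # Rarea: systolic-to-diastolic area ratio on the normalized beat
    i_p = int(round(f.t_P * sampling_rate / 1000.0))
    dt_ms = 1000.0 / sampling_rate
    denom = np.trapezoid(beat[i_p:], dx=dt_ms)
    if denom > 0 and i_p >= 1:
        Rarea = float(np.trapezoid(beat[: i_p + 1], dx=dt_ms) / denom)

    VDab = VDae = None
    if f.y_A is not None and f.y_B not in (None, 0):
        VDab = f.y_A / f.y_B
    if f.y_A is not None and f.y_E not in (None, 0):
        VDae = f.y_A / f.y_E

    return TimeFeatures(
        Tp=Tp, Td=Td, HR=HR, RI=RI, SI=SI, T_RD=T_RD,
        Rslop=Rslop, Dslop=Dslop, Rarea=Rarea, VDab=VDab, VDae=VDae,
        W25=pulse_widths(beat, f, 0.25, sampling_rate),
        W50=pulse_widths(beat, f, 0.50, sampling_rate),
        W75=pulse_widths(beat, f, 0.75, sampling_rate),
    )


# ---------------------------------------------------------------------------
# frequency domain

def welch_psd(signal: CleanSignal, segment_length: int = WELCH_SEGMENT,
              stride: int = WELCH_STRIDE, window: str = WELCH_WINDOW,
              standardize: bool = True) -> PSDEstimate:
    """Welch power-spectral-density estimate in dB.

    The signal is split into ``K = floor((N - M) / S) + 1`` segments of
    length M starting every S samples (any final partial segment is
    dropped); each segment is windowed, its periodogram normalized by the
    window energy sum, and the K periodograms are averaged and converted to
    decibels.  By default the signal is standardized to the reference RMS
    (:data:`WELCH_REFERENCE_RMS`) first, so dB values are reproducible
    across acquisition gains.
    """
    x = np.asarray(signal.samples, dtype=float)
    M, S = int(segment_length), int(stride)
    if x.size < M:
        raise ValueError(
            f"signal length {x.size} < segment length {M}; use a smaller "
            "segment length")
    if standardize:
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0) * WELCH_REFERENCE_RMS
    K = (x.size - M) // S + 1
    w = {"hann": np.hanning, "hanning": np.hanning,
         "hamming": np.hamming}[window](M)
    norm = np.sum(w ** 2)
    acc = np.zeros(M // 2 + 1)
    for k in range(K):
        seg = x[k * S: k * S + M] * w
        acc += np.abs(np.fft.rfft(seg)) ** 2 / norm
    psd = acc / K
    psd_db = 10.0 * np.log10(np.maximum(psd, 1e-300))
    freqs = np.fft.rfftfreq(M, d=1.0 / signal.sampling_rate)
    return PSDEstimate(frequencies=freqs, psd_db=psd_db, segment_length=M,
                       stride=S, window=window, segment_count=K)


def harmonic_features(psd: PSDEstimate, hr_bpm: float,
                      tol_hz: float = HARMONIC_TOL_HZ) -> HarmonicFeatures:
    """Normalized harmonic powers H1-H5 from a Welch PSD.

    The fundamental is the heart rate in Hz; the power O_k of harmonic k
    (k = 1..6) is the dB value at the PSD local maximum nearest k * f0
    within ±``tol_hz``.  H_{k-1} = O_k / O_1 for k = 2..6; a harmonic with
    no qualifying peak yields NaN.
    """
    f0 = hr_bpm / 60.0
    freqs, p = psd.frequencies, psd.psd_db
    if 6 * f0 >= freqs[-1]:
        raise ValueError("sixth harmonic beyond the PSD range")
    interior = (p[1:-1] >= p[:-2]) & (p[1:-1] >= p[2:])
    peaks = np.flatnonzero(interior) + 1
    O = np.full(6, np.nan)
    for k in range(1, 7):
        target = k * f0
        cand = peaks[np.abs(freqs[peaks] - target) <= tol_hz]
        if cand.size:
            O[k - 1] = p[cand[np.argmax(p[cand])]]
    with np.errstate(invalid="ignore", divide="ignore"):
        H = O[1:] / O[0]
    return HarmonicFeatures(fundamental_hz=f0, O=O, H=H)


# ---------------------------------------------------------------------------
# wavelet packet energies

def wpd_energies(signal: CleanSignal, wavelet: str = WPD_WAVELET,
                 level: int = WPD_LEVEL, n_bands: int = 10) -> WPDEnergies:
    """Sub-band energies from an ``level``-step wavelet packet decomposition.

    The terminal nodes are reordered from tree (Paley) order to natural
    frequency order so that node j covers
    ``[(j-1) * fs / 2**(level+1), j * fs / 2**(level+1))`` Hz; at 500 Hz and
    8 levels each of the 256 sub-bands is 0.977 Hz wide.  E1..E10 are the
    energies of the ``n_bands`` lowest bands normalized by the total energy;
    the total is also reported in dB.
    """
    x = np.asarray(signal.samples, dtype=float)
    if x.size < 2 ** level:
        raise ValueError("signal shorter than 2**level samples")
    wp = pywt.WaveletPacket(x, wavelet=wavelet, mode="periodization",
                            maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    energies = np.array([float(np.sum(node.data ** 2)) for node in nodes])
    total = float(energies.sum())
    norm = energies / total
    fs = signal.sampling_rate
    return WPDEnergies(
        level=level, node_energies=energies,
        band_width_hz=fs / 2 ** (level + 1),
        Eall_linear=total, Eall_db=10.0 * math.log10(total),
        E=norm[:n_bands],
    )


# ---------------------------------------------------------------------------
# record-level assembly

def record_feature_vector(
    signal: CleanSignal,
    onsets: OnsetTrain,
    subject: SubjectProfile | None = None,
    min_valid_beats: int = 5,
    record_id: str = "",
    event_label: int = 0,
) -> FeatureVector:
    """Extract the full 30-feature vector for one quality-passed record.

    Per-beat time-domain features are aggregated by the median over all
    annotatable beats; Welch-harmonic and wavelet-packet features are
    computed once on the whole signal.  A feature whose value could not be
    computed on any beat (or harmonic peak) is flagged missing (NaN value).
    """
    beats = segment_beats(signal, onsets)
    height = subject.height if subject is not None else None

    per_beat: list[TimeFeatures] = []
    for beat in beats:
        try:
            nb = normalize_beat(beat)
            derivs = compute_derivatives(nb, signal.sampling_rate)
            fid = annotate_beat(derivs)
        except (DegenerateBeatError, BeatRejected, ValueError):
            continue
        # widths/areas are read off the same smoothed waveform the landmark
        # rules saw, so level crossings are not triggered by residual noise
        per_beat.append(time_features(fid, derivs.ppg, signal.sampling_rate,
                                      height))
    if len(per_beat) < min_valid_beats:
        raise ValueError(
            f"only {len(per_beat)} valid beats (need {min_valid_beats})")

    values: dict[str, float] = {}
    missing: set[str] = set()
    for name in TIME_FEATURE_NAMES:
        vals = [tf.as_dict()[name] for tf in per_beat]
        vals = [v for v in vals if v is not None and np.isfinite(v)]
        if vals:
            values[name] = float(np.median(vals))
        else:
            values[name] = float("nan")
            missing.add(name)

    hr = values["HR"]
    psd = welch_psd(signal)
    try:
        harm = harmonic_features(psd, hr)
        H = harm.H
    except ValueError:
        H = np.full(5, np.nan)
    for i, name in enumerate(HARMONIC_FEATURE_NAMES):
        v = float(H[i])
        values[name] = v
        if not np.isfinite(v):
            missing.add(name)

    wpd = wpd_energies(signal)
    for i in range(10):
        values[f"E{i + 1}"] = float(wpd.E[i])
    values["Eall"] = wpd.Eall_db

    sid = subject.subject_id if subject is not None else ""
    return FeatureVector(values=values, missing=missing, subject_id=sid,
                         record_id=record_id or signal.source_record_id,
                         event_label=event_label)
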
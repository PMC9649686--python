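"""Record-level glue: raw record -> clean signal -> onsets -> feature vector."""

from __future__ import annotations

from .features import FeatureVector, record_feature_vector
from .io import PPGRecord, SubjectProfile
from .preprocess import (CleanSignal, OnsetTrain, QualityVerdict,
                         assess_quality, bandpass_filter, detect_onsets,
                         select_medium_segment)

__all__ = ["preprocess_record", "process_record", "fiducial_table"]


def fiducial_table(signal: CleanSignal, onsets: OnsetTrain):
    """One row of landmark times/amplitudes per annotatable beat.

    Suitable for writing to CSV (``df.to_csv``) for inspection and
    golden-file comparisons.
    """
    import pandas as pd

    from .fiducials import (BeatRejected, DegenerateBeatError, annotate_beat,
                            compute_derivatives, normalize_beat)
    from .preprocess import segment_beats

    rows = []
    for k, beat in enumerate(segment_beats(signal, onsets)):
        try:
            nb = normalize_beat(beat)
            fid = annotate_beat(compute_derivatives(nb, signal.sampling_rate))
        except (DegenerateBeatError, BeatRejected, ValueError):
            continue
        rows.append({"beat": k, "t_N": fid.t_N, "t_P": fid.t_P,
                     "t_D": fid.t_D, "t_A": fid.t_A, "t_B": fid.t_B,
                     "t_E": fid.t_E, "t_F": fid.t_F,
                     "t_next_N": fid.t_next_N, "y_N": fid.y_N,
                     "y_P": fid.y_P, "y_D": fid.y_D, "y_A": fid.y_A,
                     "y_B": fid.y_B, "y_E": fid.y_E,
                     "d_from_fallback": fid.d_from_fallback})
    return pd.DataFrame(rows)


def preprocess_record(record: PPGRecord) -> tuple[CleanSignal, OnsetTrain, QualityVerdict]:
    """Medium-segment selection, band-pass filter, onsets, quality verdict."""
    raw = select_medium_segment(record)
    clean = bandpass_filter(raw, record.sampling_rate, record_id=record.record_id)
    onsets = detect_onsets(clean)
    verdict = assess_quality(clean, onsets)
    return clean, onsets, verdict


def process_record(record: PPGRecord, subject: SubjectProfile | None = None,
                   require_quality: bool = True) -> FeatureVector | None:
    """Full single-record pipeline; returns ``None`` for unusable records."""
    try:
        clean, onsets, verdict = preprocess_record(record)
    except ValueError:
        return None
    if require_quality and not verdict.passed:
        return None
    try:
        return record_feature_vector(clean, onsets, subject=subject,
                                     record_id=record.record_id,
                                     event_label=record.event_label)
    except ValueError:
        return None
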
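"""Shared fixtures: synthetic signals, registries, and the calibrated cohort.

The expensive pieces (group calibration and the 200-record recovery cohort)
are session-scoped so the acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppgrisk.io import PPGRecord, SubjectProfile
from ppgrisk.preprocess import bandpass_filter, detect_onsets
from ppgrisk.simulate import (TABLE_NEGATIVE_SDS, TABLE_NEGATIVE_TARGETS,
                              calibrate_group_spec, default_pulse_params,
                              generate_pulse_train)

RECOVERY_SEED = 42
RECOVERY_N = 200


@pytest.fixture(scope="session")
def clean_train():
    """Noiseless 20 s default pulse train at 72 bpm with its ground truth."""
    params = default_pulse_params(72.0, noise_snr_db=None, hr_jitter_ms=0.0,
                                  baseline_amp=0.0)
    samples, truth = generate_pulse_train(params, 20.0, 500.0, seed=1)
    return samples, truth


@pytest.fixture(scope="session")
def clean_signal(clean_train):
    samples, _ = clean_train
    return bandpass_filter(samples, 500.0)


@pytest.fixture(scope="session")
def clean_onsets(clean_signal):
    return detect_onsets(clean_signal)


@pytest.fixture()
def subject():
    return SubjectProfile(subject_id="S0", age=61.6, height=167.4, weight=69.9,
                          sbp=127.4, dbp=80.3)


def make_record(samples: np.ndarray, subject_id: str = "S0",
                record_id: str = "R0", label: int = 0) -> PPGRecord:
    return PPGRecord(
        subject_id=subject_id, record_id=record_id,
        timestamp="2019-06-01T08:00:00", sampling_rate=500.0,
        samples=samples, segment_map=[(0, samples.size, "medium")],
        event_label=label,
        event_types=("gingival bleeding",) if label else (),
    )


@pytest.fixture(scope="session")
def negative_spec():
    """Negative-group spec calibrated to the published feature means."""
    keys = ("Td", "RI", "W50", "SI", "H1")
    return calibrate_group_spec(
        {k: TABLE_NEGATIVE_TARGETS[k] for k in keys},
        {k: TABLE_NEGATIVE_SDS[k] for k in keys},
        label="negative", seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def recovery_cohort(negative_spec):
    """200 records from the calibrated negative group, fully re-extracted.

    Returns a DataFrame of per-record feature medians (the quantities the
    planted-morphology recovery checks compare against their targets).
    """
    from ppgrisk.features import record_feature_vector

    rng = np.random.default_rng(RECOVERY_SEED)
    subject = SubjectProfile(subject_id="cal", height=167.4)
    rows = []
    for _ in range(RECOVERY_N):
        params = negative_spec.sample_params(rng)
        samples, _ = generate_pulse_train(params, 20.0, 500.0,
                                          seed=int(rng.integers(2 ** 31)))
        clean = bandpass_filter(samples, 500.0)
        onsets = detect_onsets(clean)
        try:
            fv = record_feature_vector(clean, onsets, subject=subject)
        except ValueError:
            continue
        rows.append({k: fv.values[k] for k in
                     ("Td", "RI", "W50", "SI", "H1", "Tp", "HR")})
    return pd.DataFrame(rows)
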
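"""Data model and on-disk round-tripping for PPG records and subject registries.

A record is stored as a JSON sidecar (``<id>.json``, metadata) next to a
one-column CSV of raw samples (``<id>.csv``).  A registry is a directory tree
``registry/<subject_id>/<record_id>.{json,csv}`` plus a ``subjects.csv`` with
one row per subject profile.  All indices are 0-based with half-open spans;
times are reported in milliseconds throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "HASBLED_FACTORS",
    "PPGRecord",
    "SubjectProfile",
    "CohortRegistry",
    "FormatError",
    "IntegrityError",
    "read_record",
    "write_record",
    "read_registry",
    "write_registry",
]

#: The ten clinical end-point (bleeding) event categories.
EVENT_TYPES = (
    "subcutaneous hemorrhage",
    "gingival bleeding",
    "epistaxis",
    "hematochezia",
    "black stool",
    "hematemesis",
    "hematuria",
    "retinal hemorrhage",
    "cerebral hemorrhage",
    "other",
)

#: The seven binary HAS-BLED risk factors.
HASBLED_FACTORS = (
    "hypertension",
    "abnormal_renal_liver",
    "stroke",
    "bleeding_history",
    "labile_inr",
    "age_over_65",
    "drugs_or_alcohol",
)

INTENSITIES = ("low", "medium", "high")


class FormatError(ValueError):
    """Malformed record header or registry file."""


class IntegrityError(ValueError):
    """Declared and actual content disagree (e.g. sample counts)."""


@dataclass
class PPGRecord:
    """One uploaded PPG measurement.

    ``segment_map`` lists ``(start, end, intensity)`` half-open spans marking
    the three luminous-intensity segments of the 60 s acquisition protocol.
    ``event_label`` is 1 iff the record was taken during a bleeding period,
    in which case ``event_types`` names the reported event categories.
    """

    subject_id: str
    record_id: str
    timestamp: str
    sampling_rate: float
    samples: np.ndarray
    segment_map: list[tuple[int, int, str]] = field(default_factory=list)
    event_label: int = 0
    event_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.segment_map = [(int(a), int(b), str(c)) for a, b, c in self.segment_map]
        self.event_types = tuple(self.event_types)
        self.validate()

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise FormatError("samples must be a non-empty 1-D sequence")
        n = self.samples.size
        spans = sorted((a, b) for a, b, _ in self.segment_map)
        for (a, b, lab) in self.segment_map:
            if not (0 <= a < b <= n):
                raise FormatError(f"segment span ({a}, {b}) outside [0, {n})")
            if lab not in INTENSITIES:
                raise FormatError(f"unknown intensity label {lab!r}")
        for (a1, b1), (a2, _b2) in zip(spans, spans[1:]):
            if a2 < b1:
                raise FormatError("segment spans overlap")
        if self.event_label not in (0, 1):
            raise FormatError("event_label must be 0 or 1")
        unknown = set(self.event_types) - set(EVENT_TYPES)
        if unknown:
            raise FormatError(f"unknown event types: {sorted(unknown)}")
        if bool(self.event_types) != bool(self.event_label):
            raise FormatError("event_types must be nonempty iff event_label == 1")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class SubjectProfile:
    """Demographics plus the seven HAS-BLED factors for one subject.

    Missing values are ``None`` (JSON ``null``), never zero.
    """

    subject_id: str
    age: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg
    sbp: float | None = None  # mmHg
    dbp: float | None = None  # mmHg
    bmi: float | None = None  # kg/m^2
    hasbled_factors: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.hasbled_factors) - set(HASBLED_FACTORS)
        if unknown:
            raise FormatError(f"unknown HAS-BLED factors: {sorted(unknown)}")
        if self.bmi is not None and self.height and self.weight:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise FormatError(
                    f"bmi {self.bmi} inconsistent with weight/height ({implied:.2f})"
                )

    def has_demographics(self, required: Sequence[str] = ("age", "height", "weight")) -> bool:
        return all(getattr(self, f) is not None for f in required)


@dataclass
class CohortRegistry:
    """All subject profiles plus their PPG records.

    Records whose ``subject_id`` has no profile are listed in ``orphans``.
    """

    subjects: dict[str, SubjectProfile] = field(default_factory=dict)
    records: dict[str, list[PPGRecord]] = field(default_factory=dict)

    @property
    def orphans(self) -> list[str]:
        return sorted(sid for sid in self.records if sid not in self.subjects)

    def n_records(self) -> int:
        return sum(len(v) for v in self.records.values())

    def all_records(self) -> Iterable[PPGRecord]:
        for sid in sorted(self.records):
            yield from self.records[sid]


# ---------------------------------------------------------------------------
# record I/O

_HEADER_FIELDS = ("subject_id", "record_id", "timestamp", "sampling_rate",
                  "n_samples", "segment_map", "event_label", "event_types")


def write_record(record: PPGRecord, path: str | Path) -> Path:
    """Write ``record`` as ``<path>.json`` + ``<path>.csv`` (lossless).

    ``path`` may carry either extension or none; returns the JSON path.
    """
    record.validate()
    base = Path(path).with_suffix("")
    header = {
        "subject_id": record.subject_id,
        "record_id": record.record_id,
        "timestamp": record.timestamp,
        "sampling_rate": record.sampling_rate,
        "n_samples": int(record.samples.size),
        "segment_map": [[a, b, lab] for a, b, lab in record.segment_map],
        "event_label": record.event_label,
        "event_types": list(record.event_types),
    }
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")
    # repr round-trips float64 exactly (17 significant digits)
    lines = "\n".join(repr(float(x)) for x in record.samples)
    base.with_suffix(".csv").write_text(lines + "\n")
    return json_path


def read_record(path: str | Path) -> PPGRecord:
    """Read a record written by :func:`write_record`."""
    base = Path(path).with_suffix("")
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(json_path)
    header = json.loads(json_path.read_text())
    for key in _HEADER_FIELDS:
        if key not in header:
            raise FormatError(f"record header missing field {key!r}")
    samples = np.loadtxt(base.with_suffix(".csv"), dtype=float, ndmin=1)
    if samples.size != header["n_samples"]:
        raise IntegrityError(
            f"header declares {header['n_samples']} samples, file has {samples.size}"
        )
    return PPGRecord(
        subject_id=header["subject_id"],
        record_id=header["record_id"],
        timestamp=header["timestamp"],
        sampling_rate=float(header["sampling_rate"]),
        samples=samples,
        segment_map=[tuple(s) for s in header["segment_map"]],
        event_label=int(header["event_label"]),
        event_types=tuple(header["event_types"]),
    )


# ---------------------------------------------------------------------------
# registry I/O

_PROFILE_COLS = ["subject_id", "age", "height", "weight", "sbp", "dbp", "bmi",
                 *HASBLED_FACTORS]


def write_registry(registry: CohortRegistry, root: str | Path) -> Path:
    """Write ``registry/<subject_id>/<record_id>.{json,csv}`` + ``subjects.csv``."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid in sorted(registry.subjects):
        prof = registry.subjects[sid]
        row: dict[str, object] = {
            "subject_id": sid, "age": prof.age, "height": prof.height,
            "weight": prof.weight, "sbp": prof.sbp, "dbp": prof.dbp, "bmi": prof.bmi,
        }
        for f in HASBLED_FACTORS:
            row[f] = int(prof.hasbled_factors.get(f, False))
        rows.append(row)
    pd.DataFrame(rows, columns=_PROFILE_COLS).to_csv(root / "subjects.csv", index=False)
    for sid, recs in registry.records.items():
        sdir = root / sid
        sdir.mkdir(exist_ok=True)
        for rec in recs:
            write_record(rec, sdir / rec.record_id)
    return root


def read_registry(root: str | Path) -> CohortRegistry:
    root = Path(root)
    subjects: dict[str, SubjectProfile] = {}
    table = pd.read_csv(root / "subjects.csv")
    for _, row in table.iterrows():
        def _get(col: str) -> float | None:
            v = row[col]
            return None if pd.isna(v) else float(v)
        subjects[str(row["subject_id"])] = SubjectProfile(
            subject_id=str(row["subject_id"]),
            age=_get("age"), height=_get("height"), weight=_get("weight"),
            sbp=_get("sbp"), dbp=_get("dbp"), bmi=_get("bmi"),
            hasbled_factors={f: bool(row[f]) for f in HASBLED_FACTORS},
        )
    records: dict[str, list[PPGRecord]] = {}
    for sdir in sorted(p for p in root.iterdir() if p.is_dir()):
        recs = [read_record(p) for p in sorted(sdir.glob("*.json"))]
        if recs:
            records[sdir.name] = recs
    return CohortRegistry(subjects=subjects, records=records)
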
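"""Generate a small labeled PPG cohort and write it to disk.

Builds a registry of 8 subjects with 5-10 records each (one subject with a
deliberately short measurement history, one with missing height), prints
the cohort accounting, and stores everything in the JSON+CSV registry
layout.
"""

from pathlib import Path

from ppgrisk import CohortSpec, generate_registry, write_registry

spec = CohortSpec(
    n_subjects=8,
    records_per_subject=(5, 10),
    positive_fraction=0.2,
    seed=7,
    record_seconds=20.0,
    n_short_history_subjects=1,
    n_missing_demo_subjects=1,
)
registry, truth = generate_registry(spec)

out = Path("scratch_registry")
write_registry(registry, out)

n_pos = int(truth.event_label.sum())
print(f"subjects: {len(registry.subjects)}")
print(f"records:  {registry.n_records()} ({n_pos} positive)")
print(f"written to {out}/ (per-subject folders + subjects.csv)")
print(truth.head(5).to_string(index=False))
# Each row of the ground-truth table carries the generative parameters the
# pipeline should later recover (heart rate, planted diastolic timing, ...).
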
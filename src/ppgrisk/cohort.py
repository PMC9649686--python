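"""Cohort retention filtering and negative-vs-positive group comparison.

Retention mirrors a home-monitoring study's accounting: subjects with fewer
than five uploaded records are excluded outright (insufficient compliance),
then records lacking demographics and records failing the signal-quality
gate are dropped.  Every exclusion is reconciled in a ledger.

Group comparison applies a two-sided Mann-Whitney U test per feature with a
flat p < 0.01 significance threshold (no multiple-testing correction, to
match common practice in this literature; an optional Holm flag is
provided).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortRegistry
from .preprocess import QualityVerdict

__all__ = [
    "RetentionLedger",
    "GroupComparison",
    "apply_retention_filters",
    "mann_whitney_u",
    "group_report",
]

SIGNIFICANCE_P = 0.01
EXACT_MAX_N = 12
DEFAULT_REQUIRED_DEMOGRAPHICS = ("age", "height", "weight")


@dataclass
class StageCount:
    subjects_in: int
    subjects_out: int
    records_in: int
    records_out: int


@dataclass
class RetentionLedger:
    """Per-stage subject/record counts; in = out + excluded at every stage."""

    stages: dict[str, StageCount] = field(default_factory=dict)

    def add(self, name: str, s_in: int, s_out: int, r_in: int, r_out: int) -> None:
        self.stages[name] = StageCount(s_in, s_out, r_in, r_out)

    def check_conservation(self) -> bool:
        names = list(self.stages)
        for a, b in zip(names, names[1:]):
            if self.stages[a].subjects_out != self.stages[b].subjects_in:
                return False
            if self.stages[a].records_out != self.stages[b].records_in:
                return False
        return all(
            st.subjects_out <= st.subjects_in and st.records_out <= st.records_in
            for st in self.stages.values()
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": k, "subjects_in": v.subjects_in, "subjects_out": v.subjects_out,
              "records_in": v.records_in, "records_out": v.records_out}
             for k, v in self.stages.items()]
        )


@dataclass
class GroupComparison:
    """One Table-4-style row: per-group mean ± SD, U, p and significance."""

    feature: str
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    u_statistic: float
    p_value: float
    significant: bool


def apply_retention_filters(
    registry: CohortRegistry,
    quality: dict[str, QualityVerdict],
    min_records: int = 5,
    required_demographics: tuple[str, ...] = DEFAULT_REQUIRED_DEMOGRAPHICS,
) -> tuple[CohortRegistry, RetentionLedger]:
    """Apply the three retention filters and account for every exclusion.

    Order: (1) subjects with fewer than ``min_records`` records are removed;
    (2) records of subjects missing any required demographic field are
    removed; (3) records whose quality verdict failed are removed.  The
    minimum-record filter is applied once, first — later exclusions do not
    retroactively drop a subject below the threshold.
    """
    s0, r0 = len(registry.subjects), registry.n_records()
    ledger = RetentionLedger()
    ledger.add("initial", s0, s0, r0, r0)

    # stage 1: minimum record count per subject
    kept = {sid: recs for sid, recs in registry.records.items()
            if len(recs) >= min_records}
    s1 = len(kept)
    r1 = sum(len(v) for v in kept.values())
    ledger.add("min_records", s0, s1, r0, r1)

    # stage 2: demographics present
    def _has_demo(sid: str) -> bool:
        prof = registry.subjects.get(sid)
        return prof is not None and prof.has_demographics(required_demographics)

    kept2 = {sid: recs for sid, recs in kept.items() if _has_demo(sid)}
    s2 = len(kept2)
    r2 = sum(len(v) for v in kept2.values())
    ledger.add("demographics", s1, s2, r1, r2)

    # stage 3: signal quality
    kept3: dict[str, list] = {}
    for sid, recs in kept2.items():
        good = [r for r in recs
                if quality.get(r.record_id) is not None and quality[r.record_id].passed]
        if good:
            kept3[sid] = good
    s3 = len(kept3)
    r3 = sum(len(v) for v in kept3.values())
    ledger.add("quality", s2, s3, r2, r3)
    ledger.add("final", s3, s3, r3, r3)

    filtered = CohortRegistry(
        subjects={sid: registry.subjects[sid] for sid in kept3
                  if sid in registry.subjects},
        records=kept3,
    )
    return filtered, ledger


def _exact_mann_whitney_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided p by enumerating all C(n_a + n_b, n_a) group labelings.

    Handles ties exactly; feasible for n_a + n_b <= 12 (<= 924 labelings).
    The p-value is the probability, under random labeling, that |U - mu| is
    at least as large as observed.
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    mu = na * (pooled.size - na) / 2.0
    dev_obs = abs(u_obs - mu) - 1e-12
    count = 0
    total = comb(n, na)
    ranks = stats.rankdata(pooled)
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = ranks[mask].sum() - na * (na + 1) / 2.0
        if abs(u - mu) >= dev_obs:
            count += 1
    return count / total


def mann_whitney_u(sample_a, sample_b, exact_max_n: int = EXACT_MAX_N
                   ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U the statistic of ``sample_a``.  For combined
    sizes up to ``exact_max_n`` the p-value is computed by exhaustive
    enumeration of labelings (exact even with ties); above that, the normal
    approximation with tie correction is used.  If every value in both
    samples is identical the test is vacuous and p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))
    u = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)
    if np.all(np.concatenate([a, b]) == a[0]):
        return u, 1.0
    if a.size + b.size <= exact_max_n:
        return u, _exact_mann_whitney_p(a, b, u)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)


def group_report(
    features: pd.DataFrame,
    label_col: str = "event_label",
    feature_cols: list[str] | None = None,
    alpha: float = SIGNIFICANCE_P,
    holm: bool = False,
) -> list[GroupComparison]:
    """Per-feature negative-vs-positive comparison (Table-4 shape).

    ``features`` holds one row per record with feature columns plus a binary
    label column.  Returns one :class:`GroupComparison` per feature, sorted
    by p-value.  With ``holm=True`` a Holm step-down correction is applied
    to the significance flags (the p-values themselves are unadjusted).
    """
    labels = features[label_col].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("both groups must be represented")
    if feature_cols is None:
        feature_cols = [c for c in features.columns
                        if c != label_col and features[c].dtype.kind in "fc"]
    neg = features[labels == 0]
    pos = features[labels == 1]

    rows = []
    for col in feature_cols:
        a = neg[col].dropna().to_numpy()
        b = pos[col].dropna().to_numpy()
        if a.size == 0 or b.size == 0:
            continue
        u, p = mann_whitney_u(a, b)
        rows.append(GroupComparison(
            feature=col,
            mean_neg=float(a.mean()), sd_neg=float(a.std(ddof=1)) if a.size > 1 else 0.0,
            mean_pos=float(b.mean()), sd_pos=float(b.std(ddof=1)) if b.size > 1 else 0.0,
            u_statistic=u, p_value=p, significant=p < alpha,
        ))
    rows.sort(key=lambda r: r.p_value)
    if holm:
        m = len(rows)
        still = True
        for i, r in enumerate(rows):
            still = still and r.p_value < alpha / (m - i)
            r.significant = still
    return rows
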
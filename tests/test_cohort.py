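"""Retention accounting and Mann-Whitney group comparison."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from ppgrisk.cohort import (apply_retention_filters, group_report,
                            mann_whitney_u)
from ppgrisk.io import CohortRegistry, SubjectProfile
from ppgrisk.preprocess import QualityVerdict
from tests.conftest import make_record


def _passing(n=True):
    return QualityVerdict(sqi=0.95 if n else 0.1, passed=bool(n), reasons=[])


def build_registry():
    """Three subjects: one short history, one missing height, one clean."""
    reg = CohortRegistry()
    samples = np.sin(np.linspace(0, 40, 1000))
    reg.subjects["short"] = SubjectProfile("short", age=60, height=170,
                                           weight=70)
    reg.subjects["nodem"] = SubjectProfile("nodem", age=55, height=None,
                                           weight=80)
    reg.subjects["clean"] = SubjectProfile("clean", age=65, height=165,
                                           weight=72)
    reg.records["short"] = [make_record(samples, "short", f"sR{i}")
                            for i in range(4)]
    reg.records["nodem"] = [make_record(samples, "nodem", f"nR{i}")
                            for i in range(6)]
    reg.records["clean"] = [make_record(samples, "clean", f"cR{i}")
                            for i in range(5)]
    quality = {r.record_id: _passing() for recs in reg.records.values()
               for r in recs}
    return reg, quality


class TestRetention:
    def test_constructed_registry_ledger(self):
        reg, quality = build_registry()
        filtered, ledger = apply_retention_filters(reg, quality)
        assert set(filtered.records) == {"clean"}
        st = ledger.stages
        assert (st["initial"].subjects_in, st["initial"].records_in) == (3, 15)
        # 4-record subject excluded first
        assert (st["min_records"].subjects_out,
                st["min_records"].records_out) == (2, 11)
        # then the subject with missing height
        assert (st["demographics"].subjects_out,
                st["demographics"].records_out) == (1, 5)
        assert (st["final"].subjects_out, st["final"].records_out) == (1, 5)
        assert ledger.check_conservation()

    def test_exactly_five_records_retained(self):
        reg, quality = build_registry()
        filtered, _ = apply_retention_filters(reg, quality)
        assert len(filtered.records["clean"]) == 5

    def test_failed_quality_drops_records(self):
        reg, quality = build_registry()
        quality["cR0"] = _passing(False)
        filtered, ledger = apply_retention_filters(reg, quality)
        assert len(filtered.records["clean"]) == 4
        assert ledger.check_conservation()

    def test_ledger_conservation_on_random_registries(self):
        rng = np.random.default_rng(8)
        samples = np.sin(np.linspace(0, 40, 500))
        for trial in range(5):
            reg = CohortRegistry()
            quality = {}
            for s in range(6):
                sid = f"S{s}"
                reg.subjects[sid] = SubjectProfile(
                    sid, age=60.0,
                    height=None if rng.random() < 0.3 else 170.0, weight=70.0)
                n = int(rng.integers(1, 9))
                reg.records[sid] = [make_record(samples, sid, f"{sid}R{i}")
                                    for i in range(n)]
                for r in reg.records[sid]:
                    quality[r.record_id] = _passing(rng.random() > 0.2)
            _, ledger = apply_retention_filters(reg, quality)
            assert ledger.check_conservation()


def brute_force_p(a, b, u_obs):
    """Enumeration oracle: two-sided p over all C(n, n_a) labelings.

    Counts pairwise wins directly (half credit for ties) rather than using
    ranks, so it is an independent route to the same U statistic.
    """
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    mu = na * (n - na) / 2

    def u_of(idx):
        grp_a = pooled[list(idx)]
        grp_b = np.delete(pooled, list(idx))
        wins = sum((x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b)
        return wins

    count = sum(1 for idx in combinations(range(n), na)
                if abs(u_of(idx) - mu) >= abs(u_obs - mu) - 1e-12)
    return count / comb(n, na)


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0)

    def test_fully_separated_small_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(3, 7)), int(rng.integers(3, 6))
        a = rng.integers(0, 6, size=na).astype(float)  # ties likely
        b = rng.integers(0, 6, size=nb).astype(float)
        u, p = mann_whitney_u(a, b)
        assert p == pytest.approx(brute_force_p(a, b, u))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=15), rng.normal(size=20)
        u_ab, p_ab = mann_whitney_u(a, b)
        u_ba, p_ba = mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba)

    def test_type_one_error_near_nominal(self):
        """Null rejection rate at p < 0.01 stays close to nominal."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a, b = rng.normal(size=50), rng.normal(size=50)
            _, p = mann_whitney_u(a, b)
            rejections += p < 0.01
        assert 0.003 <= rejections / reps <= 0.025


class TestGroupReport:
    def _table(self, n=120, shift=None, seed=0):
        rng = np.random.default_rng(seed)
        cols = {f"f{i}": rng.normal(size=2 * n) for i in range(30)}
        df = pd.DataFrame(cols)
        df["event_label"] = np.repeat([0, 1], n)
        if shift:
            for col, delta in shift.items():
                df.loc[df.event_label == 1, col] += delta
        return df

    def test_null_labels_rarely_significant(self):
        rows = group_report(self._table(seed=3))
        assert sum(r.significant for r in rows) <= 3  # ~30 * 0.01 * safety

    def test_planted_shifts_detected(self):
        shift = {f"f{i}": 0.8 for i in range(10)}
        rows = group_report(self._table(shift=shift, seed=4))
        sig = {r.feature for r in rows if r.significant}
        assert sig >= set(shift)

    def test_identical_groups_almost_never_significant(self):
        hits = 0
        for seed in range(10):
            rows = group_report(self._table(n=60, seed=100 + seed))
            hits += any(r.significant for r in rows)
        assert hits <= 4

    def test_single_class_raises(self):
        df = self._table()
        df["event_label"] = 0
        with pytest.raises(ValueError):
            group_report(df)

    def test_report_shape(self):
        rows = group_report(self._table(seed=5))
        assert len(rows) == 30
        assert all(0 <= r.p_value <= 1 for r in rows)
        ps = [r.p_value for r in rows]
        assert ps == sorted(ps)
        for r in rows:
            assert r.significant == (r.p_value < 0.01)
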
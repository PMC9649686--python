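"""HAS-BLED scoring, balancing, scaling, grid search and cross-validation."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from ppgrisk.io import HASBLED_FACTORS
from ppgrisk.risk import (DEFAULT_XGB_GRID, ModelConfig, downsample_balance,
                          grid_search, hasbled_score, roc_auc,
                          tenfold_evaluate, zscore_fit_apply)


class TestHasBled:
    def test_no_factors_is_low_risk(self):
        assert hasbled_score({}) == (0, "low")

    def test_three_factors_cross_into_increased_risk(self):
        score, cls = hasbled_score({"hypertension": True, "age_over_65": True,
                                    "bleeding_history": True})
        assert (score, cls) == (3, "increased")

    def test_all_factors(self):
        score, cls = hasbled_score({f: True for f in HASBLED_FACTORS})
        assert (score, cls) == (7, "increased")

    def test_boundary_is_exactly_three(self):
        """Across all 128 factor combinations, risk flips at score 3."""
        min_increased = 8
        max_low = -1
        for bits in product([False, True], repeat=7):
            factors = dict(zip(HASBLED_FACTORS, bits))
            score, cls = hasbled_score(factors)
            assert score == sum(bits)
            if cls == "increased":
                min_increased = min(min_increased, score)
            else:
                max_low = max(max_low, score)
        assert min_increased == 3
        assert max_low == 2

    def test_monotone_in_every_factor(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            factors = {f: bool(rng.integers(2)) for f in HASBLED_FACTORS}
            base, _ = hasbled_score(factors)
            for f in HASBLED_FACTORS:
                bumped = dict(factors)
                bumped[f] = True
                assert hasbled_score(bumped)[0] >= base

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError):
            hasbled_score({"smoking": True})


def labeled_table(n_pos, n_neg, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_pos + n_neg, 5))
    y = np.array([1] * n_pos + [0] * n_neg)
    X[y == 1] += separation
    df = pd.DataFrame(X, columns=[f"x{i}" for i in range(5)])
    df["event_label"] = y
    return df


class TestDownsample:
    def test_majority_reduced_to_minority_count(self):
        df = labeled_table(40, 400)
        out = downsample_balance(df, seed=1)
        counts = out["event_label"].value_counts()
        assert counts[0] == counts[1] == 40

    def test_already_balanced_is_identity(self):
        df = labeled_table(50, 50)
        out = downsample_balance(df, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_seed_reproducibility(self):
        df = labeled_table(30, 300)
        a = downsample_balance(df, seed=7)
        b = downsample_balance(df, seed=7)
        c = downsample_balance(df, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.index.equals(c.index)

    def test_sampling_without_replacement(self):
        df = labeled_table(25, 250)
        out = downsample_balance(df, seed=3)
        assert out.index.is_unique


class TestZScore:
    def test_sample_sd_convention(self):
        train = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        z, _ = zscore_fit_apply(train, train)
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_constant_column_centered_with_warning(self):
        train = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            z, _ = zscore_fit_apply(train, train)
        np.testing.assert_allclose(z["a"], 0.0)

    def test_row_at_train_mean_maps_to_zero(self):
        train = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 30.0]})
        test = pd.DataFrame({"a": [2.0], "b": [20.0]})
        _, zt = zscore_fit_apply(train, test)
        np.testing.assert_allclose(zt.to_numpy(), 0.0)

    def test_statistics_come_from_train_only(self):
        train = pd.DataFrame({"a": [0.0, 2.0]})
        test = pd.DataFrame({"a": [100.0]})
        ztr1, _ = zscore_fit_apply(train, test)
        ztr2, _ = zscore_fit_apply(train, pd.DataFrame({"a": [-5.0]}))
        pd.testing.assert_frame_equal(ztr1, ztr2)


def auc_pair_oracle(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties(self):
        _, auc = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        scores = np.round(rng.normal(size=n), 1)  # rounded: ties happen
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pair_oracle(scores, labels))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestGridSearch:
    def test_default_gradient_boosting_grid_size(self):
        size = int(np.prod([len(v) for v in DEFAULT_XGB_GRID.values()]))
        assert size == 1440

    def test_published_optimum_is_in_the_grid(self):
        assert 7 in DEFAULT_XGB_GRID["max_depth"]
        assert 0.06 in DEFAULT_XGB_GRID["learning_rate"]
        assert 0.01 in DEFAULT_XGB_GRID["gamma"]
        assert 0.7 in DEFAULT_XGB_GRID["subsample"]

    def test_single_point_grid_returns_that_point(self):
        df = labeled_table(30, 30, separation=2.0)
        cfg = ModelConfig(family="logistic", grid={"C": [1.0]}, seed=0)
        best, surface = grid_search(df, cfg)
        assert best == {"C": 1.0}
        assert len(surface) == 1

    def test_picks_best_auc_point(self):
        # an absurdly narrow RBF kernel memorizes the training fold and
        # scores held-out points at a constant, so CV AUC collapses
        df = labeled_table(40, 40, separation=1.5, seed=2)
        cfg = ModelConfig(family="support-vector",
                          grid={"gamma": [10000.0, "scale"]}, seed=0)
        best, surface = grid_search(df, cfg)
        assert best == {"gamma": "scale"}
        assert surface["mean_auc"].max() > 0.8


class TestTenFold:
    def test_separable_data_scores_near_one(self):
        df = labeled_table(60, 300, separation=4.0, seed=1)
        cfg = ModelConfig(family="logistic", seed=0)
        res = tenfold_evaluate(df, cfg, seed=0, params={"C": 1.0})
        assert res.mean_auc >= 0.99

    def test_permuted_labels_score_near_half(self):
        rng = np.random.default_rng(5)
        df = labeled_table(400, 400, separation=2.0, seed=3)
        df["event_label"] = rng.permutation(df["event_label"].to_numpy())
        cfg = ModelConfig(family="logistic", seed=0)
        res = tenfold_evaluate(df, cfg, seed=0, params={"C": 1.0})
        assert abs(res.mean_auc - 0.5) <= 0.08

    def test_ten_folds_with_confusion_counts(self):
        df = labeled_table(60, 300, separation=2.0, seed=4)
        cfg = ModelConfig(family="logistic", seed=0)
        res = tenfold_evaluate(df, cfg, seed=1, params={"C": 1.0})
        assert len(res.folds) == 10
        for fold in res.folds:
            assert fold.tp + fold.tn + fold.fp + fold.fn == 36
            assert 0.0 <= fold.auc <= 1.0
            s = res.summary()
        assert set(s) == {"auc_mean", "auc_sd", "sensitivity_mean",
                          "sensitivity_sd", "specificity_mean",
                          "specificity_sd"}

    def test_gradient_boosting_family_runs(self):
        df = labeled_table(30, 120, separation=2.0, seed=6)
        cfg = ModelConfig(family="gradient-boosting", seed=0)
        res = tenfold_evaluate(df, cfg, seed=0,
                               params={"max_depth": 3, "learning_rate": 0.1})
        assert res.mean_auc > 0.8
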
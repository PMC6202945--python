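"""Tests for balanced CV, baselines, KS comparison and mismatch."""

import numpy as np
import pandas as pd
import pytest

from motorbattery import classify
from motorbattery.classify import (
    CVConfig,
    balanced_subsample,
    cv_mismatch,
    ks_compare,
    mismatch_diagnostic,
    randomized_baseline,
    run_cv,
    sweep_features,
)


def _frame(n_control=30, n_pd=30, p=20, shift=1.5, seed=0,
           sessions_per_subject=2, subject_offset=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, s in (("control", n_control, 0.0), ("pd", n_pd, shift)):
        for i in range(n):
            off = subject_offset * rng.standard_normal(p)
            for r in range(sessions_per_subject):
                row = {"subject_id": f"{group}{i}", "group": group,
                       "sex": "male" if i % 2 else "female",
                       "session_time": float(r)}
                vals = rng.standard_normal(p) + off
                vals[:5] += s
                row.update({f"f{j}": vals[j] for j in range(p)})
                rows.append(row)
    return pd.DataFrame(rows)


class TestBalancedSubsample:
    def test_downsamples_to_minority(self):
        df = _frame(n_control=50, n_pd=20, sessions_per_subject=1)
        out = balanced_subsample(df, "control_vs_pd", np.random.default_rng(0))
        counts = out["group"].value_counts()
        assert counts["control"] == counts["pd"] == 20

    def test_equal_groups_unchanged_sizes(self):
        df = _frame(n_control=15, n_pd=15, sessions_per_subject=1)
        out = balanced_subsample(df, "control_vs_pd", np.random.default_rng(0))
        assert len(out) == 30

    def test_deterministic(self):
        df = _frame(n_control=30, n_pd=10, sessions_per_subject=1)
        a = balanced_subsample(df, "control_vs_pd", np.random.default_rng(7))
        b = balanced_subsample(df, "control_vs_pd", np.random.default_rng(7))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_raises(self):
        df = _frame(n_control=10, n_pd=10, sessions_per_subject=1)
        with pytest.raises(ValueError):
            balanced_subsample(df[df.group == "pd"], "control_vs_pd",
                               np.random.default_rng(0))


def _fast_cfg(**kw):
    base = dict(contrast="control_vs_pd", scheme="kfold10", repetitions=1,
                n_features=6, seed=5, n_trees=60, max_greedy=15)
    base.update(kw)
    return CVConfig(**base)


class TestRunCV:
    def test_separable_high_accuracy(self):
        df = _frame(shift=2.0)
        res = run_cv(df, _fast_cfg(repetitions=2))
        s = res.summary()
        assert s["sens_mean"] >= 0.9
        assert s["spec_mean"] >= 0.9

    def test_fold_sizes(self):
        df = _frame(n_control=40, n_pd=40, sessions_per_subject=1)
        res = run_cv(df, _fast_cfg())
        for rec in res.iterations:
            assert rec.n_validation in (7, 8, 9)

    def test_deterministic_under_seed(self):
        df = _frame()
        r1 = run_cv(df, _fast_cfg())
        r2 = run_cv(df, _fast_cfg())
        np.testing.assert_array_equal(r1.sensitivities, r2.sensitivities)
        np.testing.assert_array_equal(r1.specificities, r2.specificities)

    def test_loso_holds_out_whole_subject(self):
        df = _frame(n_control=8, n_pd=8, sessions_per_subject=3)
        res = run_cv(df, _fast_cfg(scheme="loso"))
        # every iteration validates on one subject's recordings
        for rec in res.iterations:
            assert 1 <= rec.n_validation <= 3

    def test_loo_first_recording_mode(self):
        df = _frame(n_control=10, n_pd=10, sessions_per_subject=3)
        cfg = _fast_cfg(scheme="loo", loo_draws=10,
                        loo_first_recording_only=True)
        res = run_cv(df, cfg)
        assert all(rec.n_validation == 1 for rec in res.iterations)
        assert len(res.iterations) == 10

    def test_undefined_rates_excluded_not_zeroed(self):
        # tiny folds will sometimes lack a class; means must ignore NaN
        df = _frame(n_control=6, n_pd=6, sessions_per_subject=1)
        res = run_cv(df, _fast_cfg())
        s = res.summary()
        assert res.n_undefined_sens + res.n_undefined_spec > 0
        assert np.isfinite(s["sens_mean"])

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            run_cv(_frame(), _fast_cfg(scheme="bootstrap"))
        with pytest.raises(ValueError):
            run_cv(_frame(), _fast_cfg(n_features=0))


class TestLeakage:
    def test_validation_label_corruption_leaves_training_artifacts(self):
        """Swapping groups of two validation-fold rows must not change
        what was fit on the training split of that iteration."""
        df = _frame(n_control=20, n_pd=20, sessions_per_subject=1, seed=3)
        cfg = _fast_cfg(repetitions=1, n_features=5)
        # reproduce the internal balanced set + first-fold assignment:
        rep_rng = np.random.default_rng([cfg.seed, 0])
        bal = balanced_subsample(df, cfg.contrast, rep_rng)
        perm = rep_rng.permutation(len(bal))
        fold0 = np.array_split(perm, 10)[0]
        val_rows = bal.iloc[fold0]
        pos = val_rows.index[val_rows["group"] == "pd"]
        neg = val_rows.index[val_rows["group"] == "control"]
        assert len(pos) and len(neg), "need both classes in fold 0"
        res1 = run_cv(df, cfg, record_artifacts=True)
        # corrupt: swap the group labels of one pos/neg validation pair
        df2 = df.copy()
        sid_pos = bal.loc[pos[0], "subject_id"]
        sid_neg = bal.loc[neg[0], "subject_id"]
        df2.loc[df2.subject_id == sid_pos, "group"] = "control"
        df2.loc[df2.subject_id == sid_neg, "group"] = "pd"
        res2 = run_cv(df2, cfg, record_artifacts=True)
        rec1 = next(r for r in res1.iterations if r.fold == 0)
        rec2 = next(r for r in res2.iterations if r.fold == 0)
        assert rec1.selected_features == rec2.selected_features
        assert rec1.train_median_checksum == rec2.train_median_checksum


class TestRandomizedBaseline:
    def test_chance_level(self):
        df = _frame(shift=2.0)
        cfg = _fast_cfg(repetitions=5)
        base = randomized_baseline(df, cfg)
        s = base.summary()
        assert s["sens_mean"] == pytest.approx(0.5, abs=0.1)
        assert s["spec_mean"] == pytest.approx(0.5, abs=0.1)

    def test_deterministic(self):
        df = _frame()
        cfg = _fast_cfg()
        b1 = randomized_baseline(df, cfg)
        b2 = randomized_baseline(df, cfg)
        np.testing.assert_array_equal(b1.sensitivities, b2.sensitivities)


class TestKSCompare:
    def test_identical_samples(self):
        a = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        stat, p = ks_compare(a, a)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = ks_compare(np.linspace(0, 0.2, 8), np.linspace(0.8, 1, 8))
        assert stat == 1.0

    def test_hand_computed_ecdf(self):
        # D = 1 for fully separated two-point samples (padded to n >= 5)
        a = np.array([0.1, 0.2, 0.15, 0.12, 0.18])
        b = np.array([0.8, 0.9, 0.85, 0.82, 0.88])
        stat, p = ks_compare(a, b)
        assert stat == 1.0
        assert p < 0.05

    def test_minimum_n(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([0.1, 0.2]), np.array([0.3, 0.4, 0.5, 0.6, 0.7]))


class TestSweep:
    def test_fifteen_points(self):
        df = _frame(p=12)
        cfg = _fast_cfg(n_trees=30)
        results = sweep_features(df, cfg)
        assert len(results) == 15
        assert [r.config.n_features for r in results] == list(range(2, 31, 2))

    def test_all_point_appended(self):
        df = _frame(p=12)
        results = sweep_features(df, _fast_cfg(n_trees=20), include_all=True)
        assert len(results) == 16
        assert results[-1].config.n_features == "all"


class TestMismatch:
    def test_subset_hull_zero(self):
        train = pd.DataFrame({"a": [0.0, 1.0, 2.0, 3.0]})
        val = pd.DataFrame({"a": [1.0, 2.0]})
        out = mismatch_diagnostic(train, val, ["a"])
        assert out["per_feature"]["a"] == 0.0

    def test_hand_counted_percentage(self):
        train = pd.DataFrame({"a": list(range(1, 10))})
        val = pd.DataFrame({"a": [0.0, 5.0, 10.0]})
        out = mismatch_diagnostic(train, val, ["a"])
        assert out["per_feature"]["a"] == pytest.approx(200.0 / 3.0)

    def test_empty_split_raises(self):
        with pytest.raises(ValueError):
            mismatch_diagnostic(pd.DataFrame({"a": []}),
                                pd.DataFrame({"a": [1.0]}), ["a"])

    def test_loso_mismatch_exceeds_kfold_with_subject_offsets(self):
        df = _frame(n_control=12, n_pd=12, sessions_per_subject=3,
                    subject_offset=3.0, seed=9)
        kf = cv_mismatch(df, _fast_cfg(repetitions=1))
        lo = cv_mismatch(df, _fast_cfg(scheme="loso", repetitions=1))
        assert lo["mean_pct"] > kf["mean_pct"]
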
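"""Feature assembly, splits, repeated/fivefold evaluation, importances."""

import numpy as np
import pandas as pd
import pytest

from gatenet.classify import (
    FEATURE_CLASSES,
    FEATURE_COLUMNS,
    PrunedTreeClassifier,
    assemble_features,
    feature_class_importance,
    run_fivefold,
    run_repeated,
    split_20pct_per_group,
)
from gatenet.synthgen import GROUPS


def synthetic_table(rng, n_per_group=(25, 23, 19), separation=0.0, net_only=False):
    """Feature table with optional planted group separation."""
    rows = []
    for g, n in zip(GROUPS, n_per_group):
        offset = {"FESZ": 0.0, "UHR": 1.0, "HC": 2.0}[g] * separation
        for k in range(n):
            row = {"subject": f"{g}{k:03d}", "group": g}
            for col in FEATURE_COLUMNS:
                signal = offset if (not net_only or col in FEATURE_CLASSES["NET"]) else 0.0
                row[col] = signal + rng.normal()
            rows.append(row)
    return pd.DataFrame(rows)


class TestAssemble:
    @staticmethod
    def sources(rng, n_per_group=(25, 23, 19)):
        subjects = [f"{g}{k:03d}" for g, n in zip(GROUPS, n_per_group) for k in range(n)]
        groups = [s[:-3] for s in subjects]
        erp = pd.DataFrame(
            {
                "subject": subjects,
                "group": groups,
                "s1_amp": rng.normal(1.2, 0.5, len(subjects)),
                "s2_amp": rng.normal(0.8, 0.4, len(subjects)),
            }
        )
        erp["diff"] = erp.s1_amp - erp.s2_amp
        erp["ratio"] = erp.s2_amp / erp.s1_amp
        net = pd.DataFrame({"subject": subjects})
        for col in FEATURE_CLASSES["NET"]:
            net[col] = rng.normal(size=len(subjects))
        cov = pd.DataFrame({"subject": subjects, "group": groups})
        for col in ("gender", "age", "education", *FEATURE_CLASSES["MCCB"]):
            cov[col] = rng.normal(size=len(subjects))
        return erp, net, cov

    def test_full_cohort_gives_67_by_24(self, rng):
        table = assemble_features(*self.sources(rng))
        assert table.shape == (67, 26)  # subject + group + 24 features
        assert list(table.columns[2:]) == list(FEATURE_COLUMNS)

    def test_feature_class_partition_sizes(self):
        sizes = [len(v) for v in FEATURE_CLASSES.values()]
        assert sizes == [4, 9, 3, 8]
        assert len(FEATURE_COLUMNS) == 24

    def test_row_order_invariance(self, rng):
        erp, net, cov = self.sources(rng)
        t1 = assemble_features(erp, net, cov)
        t2 = assemble_features(
            erp.sample(frac=1, random_state=0),
            net.sample(frac=1, random_state=1),
            cov.sample(frac=1, random_state=2),
        )
        pd.testing.assert_frame_equal(t1, t2)

    def test_missing_subject_listed(self, rng):
        erp, net, cov = self.sources(rng)
        with pytest.raises(ValueError, match="FESZ000"):
            assemble_features(erp.iloc[1:], net, cov)


class TestSplits:
    def test_study_sizes_give_14_test_53_train(self):
        labels = ["FESZ"] * 25 + ["UHR"] * 23 + ["HC"] * 19
        train, test = split_20pct_per_group(labels, seed=0)
        assert len(test) == 14 and len(train) == 53

    def test_equal_groups_of_ten(self):
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        train, test = split_20pct_per_group(labels, seed=1)
        lab = np.asarray(labels)
        assert all((lab[test] == g).sum() == 2 for g in "ABC")

    def test_partition_property(self):
        labels = ["FESZ"] * 25 + ["UHR"] * 23 + ["HC"] * 19
        train, test = split_20pct_per_group(labels, seed=3)
        assert len(np.intersect1d(train, test)) == 0
        assert len(np.union1d(train, test)) == 67

    def test_tiny_group_gets_one_test_sample(self):
        labels = ["A"] * 3 + ["B"] * 20
        _, test = split_20pct_per_group(labels, seed=0)
        assert (np.asarray(labels)[test] == "A").sum() == 1


class TestRepeated:
    def test_accuracy_list_length_101(self, rng):
        table = synthetic_table(rng, separation=3.0)
        res = run_repeated(table, n_rep=101, seed=0)
        assert len(res.accuracies) == 101

    def test_separable_features_high_accuracy(self, rng):
        table = synthetic_table(rng, separation=8.0)
        res = run_repeated(table, n_rep=21, seed=0)
        assert res.median_accuracy >= 0.95

    def test_shuffled_labels_chance_level(self, rng):
        table = synthetic_table(rng, separation=8.0)
        table["group"] = rng.permutation(table["group"].to_numpy())
        res = run_repeated(table, n_rep=21, seed=0)
        assert abs(res.median_accuracy - 1 / 3) < 0.20

    def test_confusion_rows_sum_to_test_counts(self, rng):
        table = synthetic_table(rng, separation=3.0)
        res = run_repeated(table, n_rep=5, seed=0)
        assert list(res.confusion_median.sum(axis=1)) == [5, 5, 4]

    def test_deterministic_given_seed(self, rng):
        table = synthetic_table(rng, separation=2.0)
        r1 = run_repeated(table, n_rep=7, seed=9)
        r2 = run_repeated(table, n_rep=7, seed=9)
        assert np.array_equal(r1.accuracies, r2.accuracies)


class TestFivefold:
    def test_fold_sizes_for_67_subjects(self, rng):
        table = synthetic_table(rng)
        res = run_fivefold(table, seed=0)
        assert sorted(res.fold_sizes) == [13, 13, 13, 14, 14]

    def test_identical_features_majority_rate(self, rng):
        table = synthetic_table(rng)
        table[list(FEATURE_COLUMNS)] = 1.0
        res = run_fivefold(table, seed=0)
        assert res.mean_accuracy == pytest.approx(25 / 67, abs=0.12)

    def test_same_seed_same_folds(self, rng):
        table = synthetic_table(rng, separation=1.0)
        r1 = run_fivefold(table, seed=4)
        r2 = run_fivefold(table, seed=4)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)


class TestImportance:
    def test_single_feature_tree_full_share(self):
        class Stub:
            feature_importances_ = np.eye(24)[0]

        shares = feature_class_importance(Stub())
        assert shares["ERP"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, rng):
        table = synthetic_table(rng, separation=2.0)
        res = run_repeated(table, n_rep=9, seed=0)
        assert sum(res.class_importance.values()) == pytest.approx(100.0, abs=1e-9)

    def test_net_signal_dominates_when_planted(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            table = synthetic_table(r, separation=3.0, net_only=True)
            res = run_repeated(table, n_rep=9, seed=seed)
            top = max(res.class_importance, key=res.class_importance.get)
            hits += top == "NET"
        assert hits >= 9


class TestPrunedTree:
    def test_sklearn_estimator_contract(self, rng):
        from sklearn.base import clone

        est = PrunedTreeClassifier(inner_cv=3, random_state=0)
        params = est.get_params()
        assert params["inner_cv"] == 3
        clone(est)  # must be clonable for model selection

    def test_prunes_noise_to_simpler_tree(self, rng):
        X = rng.normal(size=(120, 5))
        y = (X[:, 0] > 0).astype(int)
        est = PrunedTreeClassifier(random_state=0).fit(X, y)
        assert est.tree_.get_n_leaves() <= 8
        assert est.ccp_alpha_ >= 0.0

    def test_single_class_training_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="single class"):
            PrunedTreeClassifier().fit(X, np.zeros(10))

    def test_composes_with_sklearn_cv(self, rng):
        from sklearn.model_selection import cross_val_score

        X = rng.normal(size=(60, 4))
        y = (X[:, 1] > 0).astype(int)
        scores = cross_val_score(PrunedTreeClassifier(random_state=0), X, y, cv=3)
        assert scores.mean() > 0.7
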
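"""Three-group staging classifier on the 24-feature table.

Features come in four classes — ERP gating measures (4), graph-theoretic
network parameters (9), demographics (3) and MCCB cognitive scores (8) —
joined per subject with a FESZ/UHR/HC label.  The classifier is a
classification tree with cost-complexity post-pruning, the penalty chosen
by internal stratified cross-validation on the training set.  Two
evaluation protocols mirror the staging experiments: 101 independent
20%-per-group train/test splits summarised by the median accuracy, and a
stratified fivefold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_X_y, check_array

__all__ = [
    "FEATURE_CLASSES",
    "FEATURE_COLUMNS",
    "PrunedTreeClassifier",
    "SplitResult",
    "CVResult",
    "assemble_features",
    "split_20pct_per_group",
    "run_repeated",
    "run_fivefold",
    "feature_class_importance",
]

#: the 24 features by class, in fixed table order
FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "ERP": ("S1_Amplitude", "S2_Amplitude", "S1-S2", "S2/S1"),
    "NET": (
        "S1_CLU", "S2_CLU", "S1_S2_CLU",
        "S1_CHA", "S2_CHA", "S1_S2_CHA",
        "S1_EFF", "S2_EFF", "S1_S2_EFF",
    ),
    "DEM": ("gender", "age", "education"),
    "MCCB": ("SOPV", "AVV", "WMV", "VBLV", "VSLV", "RPSV", "SCV", "OCV"),
}
FEATURE_COLUMNS: tuple[str, ...] = sum(FEATURE_CLASSES.values(), ())

GROUP_ORDER = ("FESZ", "UHR", "HC")


class PrunedTreeClassifier(BaseEstimator, ClassifierMixin):
    """Decision tree with post-pruning selected by internal cross-validation.

    Fits an unpruned tree, computes its cost-complexity pruning path, and
    picks the pruning penalty ``ccp_alpha`` maximising mean accuracy over an
    internal stratified ``inner_cv``-fold split of the training data (ties
    favour the strongest pruning, i.e. the simplest tree).

    Parameters
    ----------
    criterion
        Impurity criterion of the underlying tree.
    inner_cv
        Number of internal folds used to select the pruning penalty.
    random_state
        Seeds both the tree and the internal fold shuffling.
    """

    def __init__(self, criterion: str = "gini", inner_cv: int = 5, random_state=None):
        self.criterion = criterion
        self.inner_cv = inner_cv
        self.random_state = random_state

    def fit(self, X, y) -> "PrunedTreeClassifier":
        X, y = check_X_y(X, y, dtype=np.float64)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training set contains a single class")

        base = DecisionTreeClassifier(
            criterion=self.criterion, random_state=self.random_state
        )
        path = base.cost_complexity_pruning_path(X, y)
        alphas = np.unique(np.maximum(path.ccp_alphas, 0.0))

        n_splits = int(min(self.inner_cv, counts.min()))
        if alphas.size > 1 and n_splits >= 2:
            cv = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=self.random_state
            )
            scores = np.zeros(alphas.size)
            for train_idx, val_idx in cv.split(X, y):
                for a_idx, a in enumerate(alphas):
                    t = DecisionTreeClassifier(
                        criterion=self.criterion,
                        random_state=self.random_state,
                        ccp_alpha=a,
                    ).fit(X[train_idx], y[train_idx])
                    scores[a_idx] += t.score(X[val_idx], y[val_idx])
            best = alphas[np.flatnonzero(scores == scores.max())[-1]]
        else:
            best = float(alphas[0]) if alphas.size else 0.0

        self.tree_ = DecisionTreeClassifier(
            criterion=self.criterion, random_state=self.random_state, ccp_alpha=best
        ).fit(X, y)
        self.ccp_alpha_ = float(best)
        self.classes_ = self.tree_.classes_
        self.feature_importances_ = self.tree_.feature_importances_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_array(X)
        return self.tree_.predict(X)

    def predict_proba(self, X):
        check_array(X)
        return self.tree_.predict_proba(X)


@dataclass
class SplitResult:
    """Repeated random-split evaluation summary."""

    accuracies: np.ndarray
    median_accuracy: float
    mean_accuracy: float
    sd_accuracy: float
    confusion_median: pd.DataFrame  # rows = true group, cols = predicted
    class_importance: dict[str, float]
    seed: int | None


@dataclass
class CVResult:
    """Stratified k-fold evaluation summary."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_sizes: list[int]
    seed: int | None


def assemble_features(
    erp_df: pd.DataFrame,
    net_df: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Join the three feature sources on subject id into the 24-column table.

    ``erp_df`` must carry subject, group, s1_amp, s2_amp, diff, ratio;
    ``net_df`` subject plus the nine network feature columns; ``covariates``
    subject plus gender/age/education and the eight MCCB columns.  Subjects
    missing from any source raise an error listing the ids.
    """
    frames = {"erp": erp_df, "net": net_df, "covariates": covariates}
    subject_sets = {k: set(v["subject"]) for k, v in frames.items()}
    common = set.intersection(*subject_sets.values())
    missing = {
        k: sorted(set.union(*subject_sets.values()) - s)
        for k, s in subject_sets.items()
        if set.union(*subject_sets.values()) - s
    }
    if missing:
        raise ValueError(f"subjects missing from sources: {missing}")

    erp = erp_df.rename(
        columns={
            "s1_amp": "S1_Amplitude",
            "s2_amp": "S2_Amplitude",
            "diff": "S1-S2",
            "ratio": "S2/S1",
        }
    )
    table = (
        erp.merge(net_df, on="subject")
        .merge(covariates.drop(columns=["group"], errors="ignore"), on="subject")
        .sort_values("subject", kind="stable")
        .reset_index(drop=True)
    )
    cols = ["subject", "group", *FEATURE_COLUMNS]
    absent = [c for c in cols if c not in table.columns]
    if absent:
        raise ValueError(f"missing feature columns: {absent}")
    out = table[cols].copy()
    # an undefined gating ratio (non-positive S1) is encoded as 0 for the tree
    out["S2/S1"] = out["S2/S1"].fillna(0.0)
    if out["group"].isna().any():
        raise ValueError("missing group labels")
    assert len(common) == len(out)
    return out


def split_20pct_per_group(
    labels, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random 20%-per-group test split (nearest integer, at least 1)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    test_idx = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        n_test = max(1, int(np.floor(0.2 * idx.size + 0.5)))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


def _xy(table: pd.DataFrame, feature_subset=None) -> tuple[np.ndarray, np.ndarray, list]:
    features = list(feature_subset) if feature_subset is not None else list(FEATURE_COLUMNS)
    X = table[features].to_numpy(dtype=np.float64)
    y = table["group"].to_numpy()
    return X, y, features


def run_repeated(
    table: pd.DataFrame,
    n_rep: int = 101,
    seed: int | None = None,
    feature_subset=None,
    estimator: PrunedTreeClassifier | None = None,
) -> SplitResult:
    """``n_rep`` independent 20%-per-group splits of a pruned tree.

    Reports the accuracy list, its mean +- SD, the median (the middle order
    statistic for odd ``n_rep``), the confusion matrix of the repetition
    achieving the median accuracy, and the impurity importance shares of
    the four feature classes pooled over all repetitions.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    X, y, features = _xy(table, feature_subset)
    base = estimator if estimator is not None else PrunedTreeClassifier()
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_rep)]

    accuracies = np.zeros(n_rep)
    confusions = []
    importance = np.zeros(len(features))
    for r in range(n_rep):
        train, test = split_20pct_per_group(y, seed=rep_seeds[r])
        est = clone(base).set_params(random_state=rep_seeds[r])
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        accuracies[r] = float(np.mean(pred == y[test]))
        order = [g for g in GROUP_ORDER if g in np.unique(y)] or list(np.unique(y))
        confusions.append(confusion_matrix(y[test], pred, labels=order))
        importance += est.feature_importances_

    sorted_acc = np.sort(accuracies)
    median = float(sorted_acc[(n_rep - 1) // 2]) if n_rep % 2 else float(
        np.median(accuracies)
    )
    median_rep = int(np.flatnonzero(accuracies == median)[0]) if median in accuracies else int(
        np.argmin(np.abs(accuracies - median))
    )
    order = [g for g in GROUP_ORDER if g in np.unique(y)] or list(np.unique(y))
    conf = pd.DataFrame(confusions[median_rep], index=order, columns=order)
    return SplitResult(
        accuracies=accuracies,
        median_accuracy=median,
        mean_accuracy=float(accuracies.mean()),
        sd_accuracy=float(accuracies.std(ddof=1)) if n_rep > 1 else 0.0,
        confusion_median=conf,
        class_importance=_class_shares(importance, features),
        seed=seed,
    )


def run_fivefold(
    table: pd.DataFrame,
    seed: int | None = None,
    feature_subset=None,
    n_splits: int = 5,
    estimator: PrunedTreeClassifier | None = None,
) -> CVResult:
    """Stratified k-fold (default fivefold) cross-validation accuracy."""
    X, y, _ = _xy(table, feature_subset)
    base = estimator if estimator is not None else PrunedTreeClassifier()
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs, sizes = [], []
    for k, (train, test) in enumerate(cv.split(X, y)):
        est = clone(base).set_params(random_state=None if seed is None else seed + k)
        est.fit(X[train], y[train])
        accs.append(float(np.mean(est.predict(X[test]) == y[test])))
        sizes.append(len(test))
    accs = np.asarray(accs)
    return CVResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        fold_sizes=sizes,
        seed=seed,
    )


def _class_shares(importance: np.ndarray, features: list) -> dict[str, float]:
    total = importance.sum()
    shares = {}
    for cls, cols in FEATURE_CLASSES.items():
        idx = [features.index(c) for c in cols if c in features]
        shares[cls] = float(importance[idx].sum() / total * 100.0) if total > 0 else 0.0
    return shares


def feature_class_importance(
    estimators, feature_names=None
) -> dict[str, float]:
    """Impurity-importance shares (%) of the four feature classes.

    ``estimators`` is one fitted tree (or :class:`PrunedTreeClassifier`) or
    a sequence of them; importances are summed before normalising to 100%.
    """
    if hasattr(estimators, "feature_importances_"):
        estimators = [estimators]
    estimators = list(estimators)
    if not estimators:
        raise ValueError("need at least one fitted tree")
    features = list(feature_names) if feature_names is not None else list(FEATURE_COLUMNS)
    importance = np.zeros(len(features))
    for est in estimators:
        importance += np.asarray(est.feature_importances_)
    return _class_shares(importance, features)
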
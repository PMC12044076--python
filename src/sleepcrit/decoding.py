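"""Condition decoding: per-channel single-feature classifiers, single-epoch
LDA with balanced accuracy, and the multi-feature random forest.

All cross-validation is grouped by subject so the two recordings of a
subject never straddle a train/test split, and the permutation null for
the single-feature classifiers swaps the condition labels *within*
random subsets of subjects — the exchangeable unit of the paired design
— with maximum-accuracy-across-channels correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.svm import SVC

DEFAULT_RF_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [None, 5, 10],
    "max_features": ["sqrt", 0.2],
}


@dataclass
class DecodeConfig:
    model: str = "svm_rbf"            # svm_rbf | lda | random_forest
    n_folds: int = 10                 # outer grouped k-fold (single-feature)
    inner_folds: int = 7              # grouped CV for RF grid search
    n_test_subjects: int = 5          # left out per RF repeat
    n_label_perm: int = 1000
    n_rf_repeats: int = 25
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    seed: int = 0


@dataclass
class DecodingResult:
    scores: np.ndarray          # per channel (single-feature) or per fold
    p_corrected: np.ndarray | None
    fold_scores: np.ndarray
    seed: int


@dataclass
class ImportanceResult:
    importance_mean: np.ndarray
    importance_sd: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    feature_names: list[str]

    def top_k(self, k: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.importance_mean)[::-1][:k]
        return [(self.feature_names[i], float(self.importance_mean[i]))
                for i in order]


def _make_classifier(model: str, seed: int = 0):
    if model == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if model == "lda":
        return LinearDiscriminantAnalysis()
    if model == "lda_shrinkage":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if model == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _check_groups(train_groups: np.ndarray, test_groups: np.ndarray) -> None:
    overlap = set(train_groups) & set(test_groups)
    if overlap:
        raise AssertionError(f"subject leakage across folds: {overlap}")


def _grouped_cv_accuracy(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                         model: str, n_folds: int,
                         balanced: bool = False) -> np.ndarray:
    """Per-fold (balanced) accuracy of a grouped k-fold CV."""
    cv = GroupKFold(n_splits=n_folds)
    scores = []
    for train, test in cv.split(x, y, groups):
        _check_groups(groups[train], groups[test])
        if len(np.unique(y[train])) < 2:
            raise ValueError("training fold missing one class")
        clf = _make_classifier(model)
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        if balanced:
            if len(np.unique(y[test])) < 2:
                raise ValueError("test fold missing one class")
            scores.append(balanced_accuracy_score(y[test], pred))
        else:
            scores.append(float(np.mean(pred == y[test])))
    return np.array(scores)


def _swap_labels_within_subjects(y: np.ndarray, groups: np.ndarray,
                                 rng: np.random.Generator) -> np.ndarray:
    """Permutation-null labels: flip both labels of a random subject subset.

    Respects the paired design — each subject keeps one sample per
    condition, only the assignment is exchanged.
    """
    y_perm = y.copy()
    for subj in np.unique(groups):
        if rng.random() < 0.5:
            sel = groups == subj
            vals = y_perm[sel]
            y_perm[sel] = vals[::-1]
    return y_perm


def decode_single_feature(values: np.ndarray, labels: np.ndarray,
                          groups: np.ndarray,
                          config: DecodeConfig = DecodeConfig()
                          ) -> DecodingResult:
    """Per-channel grouped-CV decoding with a max-stat permutation null.

    values
        (n_samples, n_channels) array of one feature across channels;
        one row per (subject, condition) sample.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    n_groups = len(np.unique(groups))
    if n_groups < config.n_folds:
        raise ValueError("fewer subjects than folds")
    n_chan = values.shape[1]

    fold_scores = np.stack([
        _grouped_cv_accuracy(values[:, [c]], labels, groups,
                             config.model, config.n_folds)
        for c in range(n_chan)
    ])
    obs = fold_scores.mean(axis=1)

    rng = np.random.default_rng(config.seed)
    null_max = np.empty(config.n_label_perm)
    for i in range(config.n_label_perm):
        y_perm = _swap_labels_within_subjects(labels, groups, rng)
        accs = [
            _grouped_cv_accuracy(values[:, [c]], y_perm, groups,
                                 config.model, config.n_folds).mean()
            for c in range(n_chan)
        ]
        null_max[i] = max(accs)
    p = (1 + (null_max[:, None] >= obs[None, :]).sum(axis=0)) \
        / (config.n_label_perm + 1)
    return DecodingResult(scores=obs, p_corrected=p,
                          fold_scores=fold_scores, seed=config.seed)


def decode_single_epoch(values: np.ndarray, labels: np.ndarray,
                        groups: np.ndarray,
                        config: DecodeConfig | None = None) -> DecodingResult:
    """Single-epoch LDA decoding scored with balanced accuracy.

    Balanced accuracy (mean of per-class recalls) is insensitive to the
    NREM/REM-driven class imbalance of epoch counts; a constant
    classifier scores exactly 0.5.
    """
    config = config or DecodeConfig(model="lda_shrinkage", n_folds=10)
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    scores = _grouped_cv_accuracy(x, np.asarray(labels), np.asarray(groups),
                                  config.model, config.n_folds, balanced=True)
    return DecodingResult(scores=np.array([scores.mean()]), p_corrected=None,
                          fold_scores=scores, seed=config.seed)


def rf_multifeature(X: np.ndarray, labels: np.ndarray, groups: np.ndarray,
                    feature_names: list[str],
                    config: DecodeConfig = DecodeConfig(model="random_forest")
                    ) -> ImportanceResult:
    """Nested-CV random forest with grid search and feature importance.

    Each repeat leaves out all samples of ``n_test_subjects`` random
    subjects, tunes hyperparameters by grouped inner-CV grid search on
    the rest, scores on the held-out subjects, and records the tuned
    forest's impurity-based feature importances (which sum to 1).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length must match X columns")
    uniq = np.unique(groups)
    if uniq.size < 2 * config.n_test_subjects:
        raise ValueError("too few subjects for the leave-k-subjects-out loop")

    rng = np.random.default_rng(config.seed)
    importances = np.empty((config.n_rf_repeats, X.shape[1]))
    accs = np.empty(config.n_rf_repeats)
    for rep in range(config.n_rf_repeats):
        test_subjects = rng.choice(uniq, size=config.n_test_subjects,
                                   replace=False)
        test_mask = np.isin(groups, test_subjects)
        _check_groups(groups[~test_mask], groups[test_mask])
        grid = GridSearchCV(
            RandomForestClassifier(
                random_state=int(rng.integers(2 ** 31))),
            param_grid=config.rf_grid,
            cv=GroupKFold(n_splits=config.inner_folds),
            scoring="accuracy", n_jobs=1,
        )
        grid.fit(X[~test_mask], labels[~test_mask],
                 groups=groups[~test_mask])
        best = grid.best_estimator_
        accs[rep] = float(np.mean(best.predict(X[test_mask])
                                  == labels[test_mask]))
        importances[rep] = best.feature_importances_
    return ImportanceResult(
        importance_mean=importances.mean(axis=0),
        importance_sd=importances.std(axis=0),
        accuracy_mean=float(accs.mean()), accuracy_sd=float(accs.std()),
        feature_names=list(feature_names),
    )
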
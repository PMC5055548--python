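"""RBF-SVM classification with inner grid search and repeated stratified CV.

Subjects are classified from their pooled feature vectors with an RBF-kernel
SVM.  Hyperparameters (C, gamma) are chosen per outer fold by an inner
stratified 5-fold grid search on the training split only (ties resolved
toward smaller C, then smaller gamma); features are z-scored with statistics
fit on the training split, as RBF distances demand.  The outer evaluation is
repeated stratified tenfold CV; accuracy, sensitivity and specificity come
from the pooled fold predictions of each repeat, AUC from the pooled
decision scores, and all are averaged across repeats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

# LIBSVM-community default grids: powers of two, step 2
_DEFAULT_C_GRID = [2.0**p for p in range(-5, 16, 2)]
_DEFAULT_GAMMA_GRID = [2.0**p for p in range(-15, 4, 2)]


@dataclass
class CVConfig:
    """Cross-validation and grid-search settings."""

    n_folds: int = 10
    n_repeats: int = 10
    stratified: bool = True
    seed: int = 0
    C_grid: list = field(default_factory=lambda: list(_DEFAULT_C_GRID))
    gamma_grid: list = field(default_factory=lambda: list(_DEFAULT_GAMMA_GRID))
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    def replace(self, **kw) -> "CVConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class CVResult:
    """Aggregated repeated-CV outcome.

    Accuracy/sensitivity/specificity are computed on the pooled fold
    predictions of each repeat (TP counts refer to the positive class,
    PsP), AUC on the pooled decision scores, then averaged over repeats.
    """

    accuracy_per_repeat: np.ndarray
    auc_per_repeat: np.ndarray
    mean_accuracy: float
    mean_auc: float
    sensitivity: float
    specificity: float
    confusion: dict
    chosen_params: list
    fold_assignments: list

    def __str__(self) -> str:
        return (
            f"CVResult(mean_accuracy={self.mean_accuracy:.3f}, mean_auc={self.mean_auc:.3f}, "
            f"sensitivity={self.sensitivity:.3f}, specificity={self.specificity:.3f})"
        )


def _fit_svm(X: np.ndarray, y: np.ndarray, C: float, gamma: float):
    # balanced class weights: cohorts are imbalanced (e.g. 13 PsP vs 22
    # TTP) and an unweighted hinge loss biases the decision threshold
    # toward the majority class
    clf = make_pipeline(
        StandardScaler(), SVC(C=C, kernel="rbf", gamma=gamma, class_weight="balanced")
    )
    clf.fit(X, y)
    return clf


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig,
    seed: int,
) -> tuple[float, float]:
    """Inner stratified k-fold grid search; returns the (C, gamma)
    maximizing inner accuracy, ties toward smaller C then smaller gamma."""
    n_min = int(np.bincount(y).min())
    n_splits = max(2, min(cv.inner_folds, n_min))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = (-1.0, None, None)
    for C in sorted(cv.C_grid):
        for gamma in sorted(cv.gamma_grid):
            correct = 0
            for tr, te in splits:
                clf = _fit_svm(X[tr], y[tr], C, gamma)
                correct += int((clf.predict(X[te]) == y[te]).sum())
            acc = correct / len(y)
            if acc > best[0]:  # strict: earlier (smaller) C/gamma win ties
                best = (acc, C, gamma)
    return best[1], best[2]


def train_eval_fold(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    cv: CVConfig,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Grid-search on the training split, refit, and score the test split.

    Returns (predictions, decision scores, chosen (C, gamma)).  Labels must
    be 0/1 with both classes present in the training split.
    """
    train_labels = np.asarray(train_labels)
    if np.unique(train_labels).size < 2:
        raise ValueError("training split contains a single class; check stratification")
    C, gamma = grid_search(train_features, train_labels, cv, seed)
    clf = _fit_svm(train_features, train_labels, C, gamma)
    pred = clf.predict(test_features)
    scores = clf.decision_function(test_features)
    return pred, scores, (C, gamma)


def roc_auc(decision_scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC: probability that a random positive outscores a random negative,
    ties counted one half (equivalently the trapezoidal ROC area)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(decision_scores, dtype=float)))


def repeated_cv(
    features: np.ndarray | None,
    labels: np.ndarray,
    cv: CVConfig | None = None,
    fold_feature_fn=None,
    select_fn=None,
) -> CVResult:
    """Repeated stratified k-fold evaluation.

    ``features`` is the subjects x F matrix for the fixed-feature path.
    For the leakage-free nested path, ``fold_feature_fn(train_idx,
    test_idx, seed)`` builds fold-specific feature matrices (e.g. from a
    dictionary learned on the training subjects only) and ``select_fn(X_train,
    y_train, seed)`` returns the selected feature columns; both hooks see
    only training data.  Fold assignments and chosen hyperparameters are
    recorded for provenance.
    """
    cv = cv or CVConfig()
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    # positive class = PsP when present, else the lexicographically later label
    positive = "PsP" if "PsP" in classes else classes[1]
    y = (labels == positive).astype(int)
    n = len(y)
    if n < cv.n_folds:
        raise ValueError(f"{n} subjects cannot fill {cv.n_folds} folds")

    ss = np.random.SeedSequence(cv.seed)
    repeat_seeds = ss.generate_state(cv.n_repeats * 2).reshape(cv.n_repeats, 2) % (2**31 - 1)

    acc_rep, auc_rep = [], []
    tp = fp = fn_ = tn = 0
    chosen, fold_assignments = [], []
    for r in range(cv.n_repeats):
        fold_seed, inner_seed = int(repeat_seeds[r, 0]), int(repeat_seeds[r, 1])
        if cv.stratified:
            skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=fold_seed)
            splits = list(skf.split(np.zeros((n, 1)), y))
        else:
            from sklearn.model_selection import KFold

            splits = list(KFold(n_splits=cv.n_folds, shuffle=True, random_state=fold_seed).split(np.zeros((n, 1))))
        preds = np.empty(n, dtype=int)
        scores = np.empty(n, dtype=float)
        for k, (tr, te) in enumerate(splits):
            if fold_feature_fn is not None:
                X_tr, X_te = fold_feature_fn(tr, te, inner_seed + k)
            else:
                X_tr, X_te = features[tr], features[te]
            if select_fn is not None:
                cols = select_fn(X_tr, labels[tr], inner_seed + k)
                X_tr, X_te = X_tr[:, cols], X_te[:, cols]
            p, s, cg = train_eval_fold(X_tr, y[tr], X_te, cv, seed=inner_seed + k)
            preds[te], scores[te] = p, s
            chosen.append(cg)
        fold_assignments.append([te.tolist() for _, te in splits])
        acc_rep.append(float((preds == y).mean()))
        auc_rep.append(roc_auc(scores, y))
        tp += int(((preds == 1) & (y == 1)).sum())
        fp += int(((preds == 1) & (y == 0)).sum())
        fn_ += int(((preds == 0) & (y == 1)).sum())
        tn += int(((preds == 0) & (y == 0)).sum())

    acc_rep = np.asarray(acc_rep)
    auc_rep = np.asarray(auc_rep)
    return CVResult(
        accuracy_per_repeat=acc_rep,
        auc_per_repeat=auc_rep,
        mean_accuracy=float(acc_rep.mean()),
        mean_auc=float(auc_rep.mean()),
        sensitivity=tp / (tp + fn_) if tp + fn_ else float("nan"),
        specificity=tn / (fp + tn) if fp + tn else float("nan"),
        confusion={"TP": tp, "FP": fp, "FN": fn_, "TN": tn},
        chosen_params=chosen,
        fold_assignments=fold_assignments,
    )
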
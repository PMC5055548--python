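"""Per-subject pooled histograms, DX-score ranking and sequential selection.

Each subject is summarized by one histogram over the Kp+Kt discriminative
atoms: bin k pools the k-th coefficient row over that subject's patch
columns.  Poolings operate on coefficient magnitudes (OMP coefficients are
signed; a large negative coefficient is as strong a contribution as a large
positive one):

    max  : max_i |b_ki|
    sqrt : sqrt( sum_i b_ki^2 / N_s )
    mean : sum_i |b_ki| / N_s
    sum  : sum_i |b_ki|
    comb : concatenation of all four

Features are ranked by the DX separability score
``DX = (m1 - m0)^2 / (d1^2 + d0^2)`` (class means and standard deviations
per feature) and selected by sequentially growing the top-ranked prefix,
scoring each prefix by stratified k-fold CV accuracy, and keeping the
smallest prefix attaining the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .encoding import DiscriminativeCodeMatrix
from .patches import PatchConfig, raw_patch_grid
from .phantom import SpatioTemporalVolume

POOLINGS = ("max", "sqrt", "mean", "sum", "comb")


@dataclass
class FeatureHistogram:
    """One subject's pooled feature vector (length Kp+Kt, or 4x that for
    the combined pooling)."""

    H: np.ndarray
    pooling: str
    subject_id: str


@dataclass
class DXRanking:
    """DX scores, the descending-score feature order, the CV accuracy curve
    over top-ranked prefixes, and the selected feature index set (smallest
    prefix attaining the curve's maximum)."""

    scores: np.ndarray
    order: np.ndarray
    accuracy_curve: np.ndarray
    selected: np.ndarray


def _pool_rows(codes: np.ndarray, method: str) -> np.ndarray:
    a = np.abs(codes)
    if method == "max":
        return a.max(axis=1)
    if method == "sqrt":
        return np.sqrt(np.mean(codes**2, axis=1))
    if method == "mean":
        return a.mean(axis=1)
    if method == "sum":
        return a.sum(axis=1)
    if method == "comb":
        return np.concatenate([_pool_rows(codes, m) for m in ("max", "sqrt", "mean", "sum")])
    raise ValueError(f"unknown pooling {method!r}; choose from {POOLINGS}")


def pool_subject(
    codes: DiscriminativeCodeMatrix | np.ndarray,
    method: str = "max",
    subject_id: str = "",
) -> FeatureHistogram:
    """Pool one subject's discriminative code columns into a histogram."""
    mat = codes.codes if isinstance(codes, DiscriminativeCodeMatrix) else np.asarray(codes, float)
    if mat.shape[1] == 0:
        raise ValueError(f"subject {subject_id!r} has zero retained patch columns")
    return FeatureHistogram(H=_pool_rows(mat, method), pooling=method, subject_id=subject_id)


def pool_cohort(
    disc: DiscriminativeCodeMatrix,
    subject_order: list[str],
    method: str = "max",
) -> np.ndarray:
    """Stack per-subject histograms into a subjects x F feature matrix,
    rows following ``subject_order``."""
    rows = []
    for sid in subject_order:
        cols = disc.for_subject(sid)
        rows.append(pool_subject(cols, method, sid).H)
    return np.vstack(rows)


def dx_scores(features: np.ndarray, labels: np.ndarray, positive_label=None) -> np.ndarray:
    """DX separability per feature: ``(m1 - m0)^2 / (d1^2 + d0^2)`` with
    unbiased (n-1) standard deviations.

    A degenerate zero denominator maps to +inf when the class means differ
    (a perfectly separating constant-within-class feature belongs at the
    top) and to 0 when they coincide.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if positive_label is None:
        positive_label = classes[0]
    pos = labels == positive_label
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("each class needs >= 2 subjects to estimate a standard deviation")
    m1, m0 = X[pos].mean(axis=0), X[~pos].mean(axis=0)
    d1, d0 = X[pos].std(axis=0, ddof=1), X[~pos].std(axis=0, ddof=1)
    num = (m1 - m0) ** 2
    den = d1**2 + d0**2
    out = np.empty(X.shape[1])
    zero_den = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[~zero_den] = num[~zero_den] / den[~zero_den]
    out[zero_den & (num > 0)] = np.inf
    out[zero_den & (num == 0)] = 0.0
    return out


def _prefix_cv_accuracy(
    X: np.ndarray,
    y01: np.ndarray,
    order: np.ndarray,
    n_folds: int,
    seed: int,
) -> np.ndarray:
    """Stratified k-fold CV accuracy of an RBF SVM on each top-ranked
    feature prefix (fixed C=1, gamma='scale': the curve compares feature
    sets, not hyperparameters)."""
    n = len(y01)
    n_folds = min(n_folds, int(np.bincount(y01).min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y01))
    curve = np.empty(len(order))
    for f, prefix_end in enumerate(range(1, len(order) + 1)):
        cols = order[:prefix_end]
        correct = 0
        for tr, te in splits:
            clf = make_pipeline(
                StandardScaler(),
                SVC(C=1.0, kernel="rbf", gamma="scale", class_weight="balanced"),
            )
            clf.fit(X[np.ix_(tr, cols)], y01[tr])
            correct += int((clf.predict(X[np.ix_(te, cols)]) == y01[te]).sum())
        curve[f] = correct / n
    return curve


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    max_prefix: int | None = None,
) -> DXRanking:
    """Rank features by DX (descending, ties by lower index) and select the
    smallest top-ranked prefix maximizing stratified k-fold CV accuracy.

    This is the ranking/selection primitive; leakage control is the
    caller's concern — the pipeline's nested mode calls it inside each
    outer training fold, while the paper-faithful mode calls it once on all
    subjects.  ``max_prefix`` optionally caps the scanned prefix length.
    """
    X = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    scores = dx_scores(X, labels)
    order = np.argsort(-scores, kind="stable")  # stable => ties keep lower index first
    if max_prefix is not None:
        order_scan = order[: max_prefix]
    else:
        order_scan = order
    classes = np.unique(labels)
    y01 = (labels == classes[1]).astype(int)
    curve = _prefix_cv_accuracy(X, y01, order_scan, n_folds, seed)
    best = int(np.argmax(curve))  # first max = smallest prefix
    return DXRanking(
        scores=scores,
        order=order,
        accuracy_curve=curve,
        selected=np.sort(order_scan[: best + 1]),
    )


def save_features(features: np.ndarray, subject_ids, labels, path) -> None:
    """Persist a subjects x F feature matrix as delimited text with a
    (subject_id, label, f0..fF-1) header."""
    import pandas as pd

    df = pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])])
    df.insert(0, "label", list(labels))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def save_ranking(ranking: DXRanking, path) -> None:
    """Persist a DX ranking: the score table and the accuracy curve as
    (prefix_size, accuracy) pairs in one delimited file."""
    lines = ["section\tindex\tvalue"]
    for i, s in enumerate(ranking.scores):
        lines.append(f"dx_score\t{i}\t{s!r}")
    for i, o in enumerate(ranking.order):
        lines.append(f"order\t{i}\t{o}")
    for i, a in enumerate(ranking.accuracy_curve, start=1):
        lines.append(f"accuracy_curve\t{i}\t{a!r}")
    for i in ranking.selected:
        lines.append(f"selected\t{i}\t1")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def mean_fa_baseline(
    volumes: list[SpatioTemporalVolume],
    patch_config: PatchConfig | None = None,
) -> np.ndarray:
    """Raw mean-FA-per-patch baseline features.

    For each subject, every patch on the stride grid contributes one
    feature: the un-normalized mean FA over its s^2*t voxels.  The same
    DX-selection and SVM path applies downstream; this is the
    immediate-FA-values control the dictionary pipeline is compared
    against.
    """
    patch_config = patch_config or PatchConfig()
    rows = []
    for vol in volumes:
        cols, _, _ = raw_patch_grid(vol.values, patch_config)
        rows.append(cols.mean(axis=0))
    return np.vstack(rows)
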
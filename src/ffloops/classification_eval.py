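"""Classification-based validation of FFL gene/miRNA sets.

The expression of the genes and miRNAs participating in a set of FFLs is used
as the feature matrix of a soft-margin SVM distinguishing sample classes
(e.g. tumor vs normal), evaluated by leave-one-out cross-validation: one SVM
per held-out sample, features z-scored with training-fold statistics.
Performance is summarized as accuracy, sensitivity, specificity and the
Matthews correlation coefficient, with an ROC built from the pooled per-fold
decision values; a label-permutation baseline calibrates chance level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .data_io import ParallelDataset

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ClassificationReport:
    acc: float
    sn: float
    sp: float
    mcc: float
    counts: ConfusionCounts | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None


def metrics_from_counts(c: ConfusionCounts) -> ClassificationReport:
    """Acc, Sn, Sp and Mcc from a confusion table.

    Acc = (TP+TN)/total, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    Mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero factor
    in the Mcc denominator yields Mcc = 0 by convention.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    if c.TP + c.FN == 0:
        raise ValueError("no positive samples: sensitivity undefined")
    if c.TN + c.FP == 0:
        raise ValueError("no negative samples: specificity undefined")
    acc = (c.TP + c.TN) / c.total
    sn = c.TP / (c.TP + c.FN)
    sp = c.TN / (c.TN + c.FP)
    denom = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    mcc = 0.0 if denom == 0 else (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom)
    return ClassificationReport(acc=acc, sn=sn, sp=sp, mcc=float(mcc), counts=c)


def roc_curve(decision_values: list[tuple[float, int]]) -> tuple[list[tuple[float, float]], float]:
    """ROC points (1-Sp, Sn) from (score, label) pairs plus the trapezoid AUC.

    The threshold sweep runs over the unique scores; with tied scores between
    classes the AUC equals the pairwise-concordance probability counting ties
    as one half.
    """
    scores = np.array([s for s, _ in decision_values], dtype=float)
    labels = np.array([y for _, y in decision_values], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes required for an ROC curve")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    points = [(0.0, 0.0)]
    # descending unique thresholds; predict positive when score >= threshold
    for thr in sorted(set(scores.tolist()), reverse=True):
        pred = scores >= thr
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        points.append((fp / n_neg, tp / n_pos))
    points.sort()
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def _feature_matrix(dataset: ParallelDataset, feature_ids: list[str]) -> tuple[np.ndarray, list[str]]:
    rows, kept = [], []
    for fid in feature_ids:
        prof = dataset.profile(fid)
        if prof is None:
            logger.warning("feature %s not measured; dropped from classifier", fid)
            continue
        rows.append(prof)
        kept.append(fid)
    if not rows:
        raise ValueError("no measured features available")
    return np.array(rows).T, kept  # samples x features


def _encode_labels(dataset: ParallelDataset, labels: dict[str, str] | None = None) -> np.ndarray:
    labels = labels if labels is not None else dataset.labels
    if labels is None:
        raise ValueError("dataset has no sample labels")
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    # the lexicographically larger class is the positive one
    return np.array([int(labels[s] == classes[1]) for s in dataset.sample_ids])


def loocv_svm(
    dataset: ParallelDataset,
    feature_ids: list[str],
    kernel: str = "linear",
    C: float = 1.0,
    labels: dict[str, str] | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated SVM over an FFL feature set.

    Each fold trains on all but one sample (features z-scored with training
    statistics) and predicts the held-out one; confusion counts and pooled
    decision values accumulate over folds.
    """
    X, _ = _feature_matrix(dataset, feature_ids)
    y = _encode_labels(dataset, labels)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("each class needs at least 2 samples for LOOCV")
    n = len(y)
    preds = np.empty(n, dtype=int)
    decisions = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[mask] - mu) / sd
        Xte = (X[i : i + 1] - mu) / sd
        clf = SVC(kernel=kernel, C=C)
        clf.fit(Xtr, y[mask])
        preds[i] = clf.predict(Xte)[0]
        decisions[i] = clf.decision_function(Xte)[0]
    counts = ConfusionCounts(
        TP=int(((preds == 1) & (y == 1)).sum()),
        TN=int(((preds == 0) & (y == 0)).sum()),
        FP=int(((preds == 1) & (y == 0)).sum()),
        FN=int(((preds == 0) & (y == 1)).sum()),
    )
    report = metrics_from_counts(counts)
    report.roc_points, report.auc = roc_curve(
        list(zip(decisions.tolist(), y.tolist()))
    )
    return report


def permutation_baseline(
    dataset: ParallelDataset,
    feature_ids: list[str],
    n_perm: int = 100,
    seed: int | None = None,
    kernel: str = "linear",
    C: float = 1.0,
) -> ClassificationReport:
    """Chance-level baseline: LOOCV metrics averaged over label permutations."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if dataset.labels is None:
        raise ValueError("dataset has no sample labels")
    rng = np.random.default_rng(seed)
    samples = dataset.sample_ids
    values = [dataset.labels[s] for s in samples]
    accs, sns, sps, mccs = [], [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        shuffled = {s: values[j] for s, j in zip(samples, perm)}
        rep = loocv_svm(dataset, feature_ids, kernel=kernel, C=C, labels=shuffled)
        accs.append(rep.acc)
        sns.append(rep.sn)
        sps.append(rep.sp)
        mccs.append(rep.mcc)
    return ClassificationReport(
        acc=float(np.mean(accs)), sn=float(np.mean(sns)),
        sp=float(np.mean(sps)), mcc=float(np.mean(mccs)),
    )
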
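"""Linear SVM training, stratified k-fold evaluation, and ablation protocols.

The classifier is a linear-kernel maximum-margin SVM with penalty C = 2
(one-vs-one voting for more than two classes).  Evaluation is stratified
10-fold cross-validation; within each fold the PCANet filter banks and the
SVM (and the feature standardizer) are fitted on the training folds only,
so no information from test epochs reaches the learned representation.

Metrics follow the usual clinical convention: accuracy is the trace of the
confusion matrix over its total; for two classes, sensitivity is the
true-positive rate of the designated stress class and specificity the
true-negative rate of the other; for three or more classes both are
macro-averaged one-vs-rest rates.  All are reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import pcanet
from .io_formats import get_logger

__all__ = [
    "EvalReport",
    "train_svm",
    "crossval",
    "crossval_images",
    "metrics",
    "ablation_single_vs_multi",
    "ABLATION_KEYS",
]

_log = get_logger("classify")

ABLATION_KEYS = ("T-TrEn", "TF-TrEn", "F-TrEn", "Multi-TrEn")


@dataclass
class EvalReport:
    """Cross-validation outcome: per-fold and mean metrics plus the pooled
    confusion matrix (rows = true class, columns = predicted)."""

    fold_accuracy: list[float]
    fold_sensitivity: list[float]
    fold_specificity: list[float]
    confusion: np.ndarray
    classes: list[str]
    positive_class: str
    folds: int
    seed: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        for seq in (self.fold_accuracy, self.fold_sensitivity, self.fold_specificity):
            if any(not (0.0 <= v <= 100.0) for v in seq):
                raise ValueError("metrics must lie in [0, 100] percent")

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sensitivity(self) -> float:
        return float(np.mean(self.fold_sensitivity))

    @property
    def specificity(self) -> float:
        return float(np.mean(self.fold_specificity))

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fold_accuracy": self.fold_accuracy,
            "fold_sensitivity": self.fold_sensitivity,
            "fold_specificity": self.fold_specificity,
            "confusion": self.confusion.tolist(),
            "classes": self.classes,
            "positive_class": self.positive_class,
            "folds": self.folds,
            "seed": self.seed,
            "config": self.config,
        }


def train_svm(features: np.ndarray, labels: Sequence[str], C: float = 2.0) -> SVC:
    """Fit a linear-kernel SVM (one-vs-one for >2 classes).

    Deterministic for fixed inputs; requires at least two classes with at
    least two samples each.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need ≥ 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("every class needs ≥ 2 samples")
    clf = SVC(kernel="linear", C=C)
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def metrics(confusion: np.ndarray, positive_class: int = 1) -> tuple[float, float, float]:
    """(Accuracy, Sensitivity, Specificity) in percent from a confusion matrix.

    ``confusion[i, j]`` counts true class i predicted as j;
    ``positive_class`` is the row/column index of the stress class.  Binary:
    Sen = TP/(TP+FN), Spe = TN/(TN+FP).  Multi-class: macro-averaged
    one-vs-rest sensitivity and specificity.
    """
    cm = np.asarray(confusion, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion must be a nonempty square matrix")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty (all counts zero)")
    acc = np.trace(cm) / total
    n = cm.shape[0]
    if n == 2:
        p = positive_class
        q = 1 - p
        tp, fn = cm[p, p], cm[p, q]
        tn, fp = cm[q, q], cm[q, p]
        sen = tp / (tp + fn) if tp + fn > 0 else 0.0
        spe = tn / (tn + fp) if tn + fp > 0 else 0.0
    else:
        sens, spes = [], []
        for c in range(n):
            tp = cm[c, c]
            fn = cm[c].sum() - tp
            fp = cm[:, c].sum() - tp
            tn = total - tp - fn - fp
            sens.append(tp / (tp + fn) if tp + fn > 0 else 0.0)
            spes.append(tn / (tn + fp) if tn + fp > 0 else 0.0)
        sen = float(np.mean(sens))
        spe = float(np.mean(spes))
    return 100.0 * acc, 100.0 * sen, 100.0 * spe


def _positive_index(classes: np.ndarray, positive_class: str | None) -> int:
    if positive_class is None:
        # default: last class in sorted order plays the stress role
        return len(classes) - 1
    idx = np.flatnonzero(classes == positive_class)
    if idx.size == 0:
        raise ValueError(f"positive class {positive_class!r} not among {list(classes)}")
    return int(idx[0])


def crossval(
    features: np.ndarray,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    C: float = 2.0,
    positive_class: str | None = None,
) -> EvalReport:
    """Stratified k-fold CV of the linear SVM on precomputed features.

    Features are standardized with training-fold statistics inside each
    fold.  Every class must have at least ``folds`` samples.
    """
    return _crossval_impl(
        np.asarray(features, dtype=float), labels, folds, seed, C, positive_class,
        extractor=None,
    )


def crossval_images(
    images: np.ndarray,
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    C: float = 2.0,
    positive_class: str | None = None,
    pcanet_kwargs: dict | None = None,
) -> EvalReport:
    """Stratified k-fold CV with per-fold PCANet refitting.

    ``images`` is (n_epochs, m, n) connectivity images.  Within each fold
    the PCANet filter banks are learned from the training images only, then
    train and test images are featurized with that fold's model.
    """
    kw = pcanet_kwargs or {}

    def extractor(train_imgs: np.ndarray, test_imgs: np.ndarray):
        model = pcanet.fit(train_imgs, **kw)
        return (
            pcanet.transform_many(model, train_imgs).astype(float),
            pcanet.transform_many(model, test_imgs).astype(float),
        )

    return _crossval_impl(
        np.asarray(images, dtype=float), labels, folds, seed, C, positive_class,
        extractor=extractor,
    )


def _crossval_impl(
    X: np.ndarray,
    labels: Sequence[str],
    folds: int,
    seed: int,
    C: float,
    positive_class: str | None,
    extractor: Callable | None,
) -> EvalReport:
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need ≥ 2 classes for cross-validation")
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; stratified "
            f"{folds}-fold CV needs ≥ {folds} per class"
        )
    pos = _positive_index(classes, positive_class)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc, fold_sen, fold_spe = [], [], []
    for fold_no, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if extractor is not None:
            Xtr, Xte = extractor(X[tr], X[te])
        else:
            Xtr, Xte = X[tr], X[te]
        scaler = StandardScaler().fit(Xtr)
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(Xtr), y[tr])
        pred = clf.predict(scaler.transform(Xte))
        cm = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y[te], pred):
            cm[class_to_idx[t], class_to_idx[p]] += 1
        confusion += cm
        a, s, sp = metrics(cm, pos)
        fold_acc.append(a)
        fold_sen.append(s)
        fold_spe.append(sp)
        _log.info("fold %d/%d: acc=%.2f%% sen=%.2f%% spe=%.2f%%", fold_no + 1, folds, a, s, sp)
    return EvalReport(
        fold_accuracy=fold_acc,
        fold_sensitivity=fold_sen,
        fold_specificity=fold_spe,
        confusion=confusion,
        classes=[str(c) for c in classes],
        positive_class=str(classes[pos]),
        folds=folds,
        seed=seed,
        config={"C": C, "refit_pcanet_per_fold": extractor is not None},
    )


def ablation_single_vs_multi(
    images: np.ndarray,
    domain_order: Sequence[float],
    labels: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    C: float = 2.0,
    positive_class: str | None = None,
    pcanet_kwargs: dict | None = None,
) -> dict[str, EvalReport]:
    """Compare single-domain connectivity matrices against the cascaded image.

    ``images`` is the stack of cascaded (channels × channels·3) images at
    orders (0, 0.5, 1).  Runs four CVs — time-domain (T-TrEn),
    time–frequency (TF-TrEn), frequency (F-TrEn) blocks, and the full
    Multi-TrEn image — with identical fold assignments (same seed).
    """
    images = np.asarray(images, dtype=float)
    n_dom = len(domain_order)
    if n_dom != 3:
        raise ValueError("ablation expects the three standard domains (p = 0, 0.5, 1)")
    n_ch = images.shape[1]
    if images.shape[2] != n_ch * n_dom:
        raise ValueError("images are not cascaded over the stated domains")
    runs: dict[str, np.ndarray] = {
        "T-TrEn": images[:, :, 0 * n_ch:1 * n_ch],
        "TF-TrEn": images[:, :, 1 * n_ch:2 * n_ch],
        "F-TrEn": images[:, :, 2 * n_ch:3 * n_ch],
        "Multi-TrEn": images,
    }
    out: dict[str, EvalReport] = {}
    for key, imgs in runs.items():
        _log.info("ablation run %s: image shape %s", key, imgs.shape[1:])
        out[key] = crossval_images(
            imgs, labels, folds=folds, seed=seed, C=C,
            positive_class=positive_class, pcanet_kwargs=pcanet_kwargs,
        )
    return out
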
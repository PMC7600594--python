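"""Classifier bank, 10-fold cross-validation, and the bespoke metrics.

Each patient's optimized 375-value vector is cut into five consecutive
frames of 75 values; frames inherit the patient's label, giving 5
instances per patient.  Six classifiers are supported: logistic
regression (LR), Fisher linear discriminant (FLDA), K-nearest neighbors
with K=5 (KNN), a 75-30-1 radial-basis-function network (RBF; k-means
centers, least-squares linear output), a 75-25-1 tanh/logistic multilayer
perceptron (MLP), and an RBF-kernel support vector machine with gamma
selected on 0.001..0.01 by inner 3-fold cross-validation (SVM_RBF).

Metrics are computed from the count primitives PC (perfect
classifications of the reported class), MC (missed classifications) and
FA (false alarms), using the published formulas *as printed*:

    Sensitivity = PC/(PC+FA) x 100        Specificity = PC/(PC+MC) x 100
    Accuracy    = (Sensitivity+Specificity)/2
    PI          = (PC-MC-FA)/PC x 100     GDR = (PC-MC)/(PC+FA) x 100

Note these deliberately differ from the textbook sensitivity/specificity
definitions; PI can be negative when errors exceed correct calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

CLASSIFIERS = ("LR", "FLDA", "KNN", "RBF", "MLP", "SVM_RBF")
POSITIVE_CLASS = "cvd"
FRAME_LENGTH = 75
VECTOR_LENGTH = 375
SVM_GAMMA_GRID = tuple(np.round(np.linspace(0.001, 0.01, 10), 4))
SVM_MAX_SUPPORT_VECTORS = 1800


@dataclass
class InstanceSet:
    """Frames of 75 values with labels and patient provenance."""

    X: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.patient_ids = np.asarray(self.patient_ids)
        if self.X.ndim != 2 or self.X.shape[1] != FRAME_LENGTH:
            raise ValueError(f"instances must have {FRAME_LENGTH} columns")
        if len(self.y) != len(self.X) or len(self.patient_ids) != len(self.X):
            raise ValueError("X, y and patient_ids must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "InstanceSet":
        return InstanceSet(self.X[idx], self.y[idx], self.patient_ids[idx])


@dataclass(frozen=True)
class ClassReport:
    """Counts and derived metrics for one reported class."""

    label: str
    PC: int
    MC: int
    FA: int
    sensitivity: float
    specificity: float
    accuracy: float
    PI: float
    GDR: float
    MSE: float


def frame_instances(
    vectors: Dict[str, np.ndarray], labels: Dict[str, str]
) -> InstanceSet:
    """Cut each patient's 375-vector into 5 labeled frames of 75 values."""
    xs, ys, pids = [], [], []
    for pid, vec in vectors.items():
        v = np.asarray(vec, dtype=float).ravel()
        if v.size != VECTOR_LENGTH:
            raise ValueError(
                f"patient {pid}: expected a {VECTOR_LENGTH}-value vector, got {v.size}"
            )
        frames = v.reshape(VECTOR_LENGTH // FRAME_LENGTH, FRAME_LENGTH)
        for fr in frames:
            xs.append(fr)
            ys.append(labels[pid])
            pids.append(pid)
    return InstanceSet(np.asarray(xs), np.asarray(ys), np.asarray(pids))


class RBFNetwork:
    """75-30-1 radial basis function network.

    Hidden centers from k-means on the training set, a shared Gaussian
    width equal to the mean inter-center distance, and a linear output
    layer fit by least squares to 0/1 targets; threshold 0.5.
    """

    def __init__(self, n_centers: int = 30, seed: int = 0):
        self.n_centers = n_centers
        self.seed = seed

    def fit(self, X: np.ndarray, y01: np.ndarray) -> "RBFNetwork":
        k = min(self.n_centers, len(X))
        km = KMeans(n_clusters=k, n_init=10, random_state=self.seed)
        km.fit(X)
        self.centers_ = km.cluster_centers_
        if k > 1:
            diff = self.centers_[:, None, :] - self.centers_[None, :, :]
            dists = np.sqrt((diff**2).sum(-1))
            self.width_ = dists[np.triu_indices(k, 1)].mean()
        else:
            self.width_ = 1.0
        if self.width_ <= 0:
            self.width_ = 1.0
        phi = self._design(X)
        self.weights_, *_ = np.linalg.lstsq(phi, y01, rcond=None)
        return self

    def _design(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.centers_[None, :, :]) ** 2).sum(-1)
        phi = np.exp(-d2 / (2 * self.width_**2))
        return np.hstack([phi, np.ones((len(X), 1))])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._design(X) @ self.weights_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)


def _select_svm_gamma(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    """Inner 3-fold CV over the gamma grid; ties go to the smaller gamma."""
    best_gamma, best_acc = SVM_GAMMA_GRID[0], -1.0
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    for gamma in SVM_GAMMA_GRID:
        correct = 0
        for tr, te in folds:
            clf = SVC(kernel="rbf", gamma=gamma, C=1.0)
            clf.fit(X[tr], y[tr])
            correct += int((clf.predict(X[te]) == y[te]).sum())
        acc = correct / len(X)
        if acc > best_acc:
            best_acc, best_gamma = acc, gamma
    return best_gamma


def fit_predict(
    classifier_name: str,
    train: InstanceSet,
    test: InstanceSet,
    seed: int = 0,
    return_scores: bool = False,
):
    """Train one classifier and predict the test set.

    Returns predicted labels, or (labels, scores) with ``return_scores``;
    scores are continuous outputs in [0, 1] (membership of the positive
    class) where the model provides them.
    """
    if classifier_name not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier_name!r}")
    classes = np.unique(train.y)
    if len(classes) < 2:
        raise ValueError("training fold contains a single class")
    y01 = (train.y == POSITIVE_CLASS).astype(int)
    neg = [c for c in classes if c != POSITIVE_CLASS][0]

    def to_labels(pred01: np.ndarray) -> np.ndarray:
        return np.where(pred01 == 1, POSITIVE_CLASS, neg)

    if classifier_name == "LR":
        clf = LogisticRegression(max_iter=1000)
        clf.fit(train.X, y01)
        scores = clf.predict_proba(test.X)[:, 1]
        pred = (scores >= 0.5).astype(int)
    elif classifier_name == "FLDA":
        clf = LinearDiscriminantAnalysis()
        clf.fit(train.X, y01)
        scores = clf.predict_proba(test.X)[:, 1]
        pred = clf.predict(test.X)
    elif classifier_name == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5)
        clf.fit(train.X, y01)
        scores = clf.predict_proba(test.X)[:, 1]
        # majority vote; a 5-neighbor tie cannot occur in binary labels,
        # but the declared rule (ties -> positive class) is kept explicit
        pred = (scores >= 0.5).astype(int)
    elif classifier_name == "RBF":
        clf = RBFNetwork(n_centers=30, seed=seed).fit(train.X, y01.astype(float))
        raw = clf.decision_function(test.X)
        scores = np.clip(raw, 0.0, 1.0)
        pred = (raw >= 0.5).astype(int)
    elif classifier_name == "MLP":
        clf = MLPClassifier(
            hidden_layer_sizes=(25,),
            activation="tanh",
            solver="lbfgs",
            max_iter=2000,
            tol=1e-6,
            random_state=seed,
        )
        clf.fit(train.X, y01)
        scores = clf.predict_proba(test.X)[:, 1]
        pred = (scores >= 0.5).astype(int)
    else:  # SVM_RBF
        # the published gamma range presumes unit-scale inputs; z-score
        # with training statistics so the kernel width is meaningful
        mu, sd = train.X.mean(axis=0), train.X.std(axis=0)
        sd[sd == 0] = 1.0
        X, y = (train.X - mu) / sd, y01
        Xt = (test.X - mu) / sd
        gamma = _select_svm_gamma(X, y, seed)
        clf = SVC(kernel="rbf", gamma=gamma, C=1.0)
        clf.fit(X, y)
        if clf.n_support_.sum() > SVM_MAX_SUPPORT_VECTORS:
            # cap the machine size by subsampling the training set
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(X), SVM_MAX_SUPPORT_VECTORS, replace=False)
            clf = SVC(kernel="rbf", gamma=gamma, C=1.0)
            clf.fit(X[keep], y[keep])
        raw = clf.decision_function(Xt)
        scores = 1.0 / (1.0 + np.exp(-raw))  # deterministic sigmoid squash
        pred = (raw >= 0).astype(int)

    labels = to_labels(np.asarray(pred))
    if return_scores:
        return labels, np.asarray(scores, dtype=float)
    return labels


def metric_formulas(
    PC: int, MC: int, FA: int
) -> Tuple[float, float, float, float, float]:
    """(sensitivity, specificity, accuracy, PI, GDR) exactly as printed.

    Undefined ratios (zero denominators) are reported as NaN.
    """
    sens = PC / (PC + FA) * 100 if PC + FA > 0 else math.nan
    spec = PC / (PC + MC) * 100 if PC + MC > 0 else math.nan
    acc = (sens + spec) / 2
    pi = (PC - MC - FA) / PC * 100 if PC > 0 else math.nan
    gdr = (PC - MC) / (PC + FA) * 100 if PC + FA > 0 else math.nan
    return sens, spec, acc, pi, gdr


def _class_counts(
    y_true: np.ndarray, y_pred: np.ndarray, label: str
) -> Tuple[int, int, int]:
    is_c = y_true == label
    pc = int(((y_pred == label) & is_c).sum())
    mc = int(((y_pred != label) & is_c).sum())
    fa = int(((y_pred == label) & ~is_c).sum())
    return pc, mc, fa


def cross_validate(
    instances: InstanceSet,
    classifier_name: str,
    folds: int = 10,
    seed: int = 0,
    targets: Dict[str, float] | None = None,
    group_by_patient: bool = False,
) -> Dict[str, ClassReport]:
    """Stratified k-fold CV; reports per class plus an 'average' entry.

    PC/MC/FA are tallied over the pooled out-of-fold predictions.  The
    Eq-style MSE compares each instance's continuous output, mapped onto
    the segment between the two class target-code values, against its
    true class's target (``targets``: label -> target value; defaults to
    the class code-value extremes when not supplied).
    """
    classes = sorted(np.unique(instances.y))
    if len(classes) != 2:
        raise ValueError("cross_validate expects exactly two classes")
    for c in classes:
        if (instances.y == c).sum() < folds:
            raise ValueError(f"class {c!r} has fewer instances than folds")
    if targets is None:
        from .codewords import VALUE_MAX, VALUE_MIN

        neg = [c for c in classes if c != POSITIVE_CLASS][0]
        targets = {neg: VALUE_MIN, POSITIVE_CLASS: VALUE_MAX}

    if group_by_patient:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(instances.X, instances.y, groups=instances.patient_ids)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(instances.X, instances.y)

    y_pred = np.empty(len(instances), dtype=instances.y.dtype)
    scores = np.empty(len(instances))
    seen = np.zeros(len(instances), dtype=bool)
    for k, (tr, te) in enumerate(split):
        labels, sc = fit_predict(
            classifier_name,
            instances.subset(tr),
            instances.subset(te),
            seed=seed + k,
            return_scores=True,
        )
        y_pred[te] = labels
        scores[te] = sc
        seen[te] = True
    assert seen.all(), "every instance must be predicted exactly once"

    neg = [c for c in classes if c != POSITIVE_CLASS][0]
    t_lo, t_hi = targets[neg], targets[POSITIVE_CLASS]
    mapped = t_lo + scores * (t_hi - t_lo)

    reports: Dict[str, ClassReport] = {}
    for c in classes:
        pc, mc, fa = _class_counts(instances.y, y_pred, c)
        sens, spec, acc, pi, gdr = metric_formulas(pc, mc, fa)
        mask = instances.y == c
        mse = float(((mapped[mask] - targets[c]) ** 2).mean())
        reports[c] = ClassReport(c, pc, mc, fa, sens, spec, acc, pi, gdr, mse)
    reports["average"] = ClassReport(
        "average",
        sum(reports[c].PC for c in classes),
        sum(reports[c].MC for c in classes),
        sum(reports[c].FA for c in classes),
        *[
            float(np.mean([getattr(reports[c], m) for c in classes]))
            for m in ("sensitivity", "specificity", "accuracy", "PI", "GDR", "MSE")
        ],
    )
    return reports


def reports_to_frame(
    reports: Dict[Tuple[str, str], Dict[str, ClassReport]]
) -> pd.DataFrame:
    """Flatten {(optimizer, classifier): {class: report}} into a table."""
    rows = []
    for (opt, clf), per_class in reports.items():
        for label, rep in per_class.items():
            rows.append(
                {
                    "optimizer": opt,
                    "classifier": clf,
                    "class": label,
                    "PC": rep.PC,
                    "MC": rep.MC,
                    "FA": rep.FA,
                    "sensitivity": rep.sensitivity,
                    "specificity": rep.specificity,
                    "accuracy": rep.accuracy,
                    "PI": rep.PI,
                    "GDR": rep.GDR,
                    "MSE": rep.MSE,
                }
            )
    return pd.DataFrame(rows)
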
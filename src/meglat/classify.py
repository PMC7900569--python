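"""Linear-SVM lateralization from the 28 laterality-index features.

The classifier follows a deliberately minimal protocol: the 28 regional
laterality indices (7 bands x 4 regions) are standardized over the dataset,
a linear support vector machine with fixed hyperparameters (C = 1, no class
weighting) is evaluated with leave-one-out cross-validation in two binary
scenarios — left-focus patients vs controls and right-focus patients vs
controls — and summarized by a confusion matrix (accuracy, sensitivity,
specificity) and a ROC curve over posterior probabilities with trapezoidal
AUC. Posterior probabilities come from a Platt sigmoid fitted on the training
fold's decision values (smoothed targets, unregularized 2-parameter logistic
MLE), so the test sample never influences its own calibration.

Standardizing over the whole dataset before cross-validation reproduces the
original protocol but leaks scaling information across folds; a ``per_fold``
option fits the scaler inside each training fold instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import LeaveOneOut
from sklearn.svm import SVC

from .bands import GROUP_CTR, GROUP_LT, GROUP_RT

__all__ = [
    "ClassifierSpec",
    "ConfusionMatrix",
    "RocCurve",
    "ConcordanceSummary",
    "standardize_features",
    "loocv_classify",
    "confusion_metrics",
    "confusion_from_rates",
    "roc_auc",
    "ecd_concordance",
    "run_scenario",
]

SCENARIOS = {
    "Lt_vs_CTR": (GROUP_LT, GROUP_CTR),
    "Rt_vs_CTR": (GROUP_RT, GROUP_CTR),
}


@dataclass
class ClassifierSpec:
    """Fixed classifier configuration (linear kernel, no tuning loop)."""

    kernel: str = "linear"
    box_constraint: float = 1.0
    scenario: str = "Lt_vs_CTR"
    standardization: str = "whole_dataset"  # or "per_fold"

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {sorted(SCENARIOS)}")
        if self.standardization not in ("whole_dataset", "per_fold"):
            raise ValueError("standardization must be 'whole_dataset' or 'per_fold'")


def standardize_features(X) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring with the population (ddof=0) standard deviation.

    Returns (Z, mean, scale). A zero-variance column is an error naming the
    offending feature(s): such a predictor carries no information and would
    blow up the scaling.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)  # population SD
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        which = [names[j] if names else int(j) for j in zero]
        raise ValueError(f"constant feature column(s): {which}")
    return (X - mean) / scale, mean, scale


def _platt_sigmoid(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit P(y=1 | d) = sigmoid(A*d + B) by MLE with Platt's smoothed targets."""
    n_pos = int(np.sum(y == 1))
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * decision + b
        # log-loss written stably via logaddexp
        return np.sum(np.logaddexp(0.0, z) - t * z)

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="BFGS")
    return float(res.x[0]), float(res.x[1])


def loocv_classify(
    features,
    labels,
    spec: ClassifierSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out cross-validation of the linear SVM.

    ``labels`` must be binary with 1 marking the patient (positive) class.
    Runs exactly n iterations; each sample is predicted once by a model that
    never saw it. Returns a DataFrame with columns (label, predicted,
    posterior, decision), indexed like the input features.

    ``seed`` is accepted for interface uniformity; the procedure is
    deterministic.
    """
    index = features.index if isinstance(features, pd.DataFrame) else None
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != len(y):
        raise ValueError("features and labels must align")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 subjects per class")

    if spec.standardization == "whole_dataset":
        X, _, _ = standardize_features(X)

    n = len(y)
    pred = np.empty(n, dtype=int)
    post = np.empty(n)
    decision = np.empty(n)
    for train_idx, test_idx in LeaveOneOut().split(X):
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("a training fold lost an entire class")
        X_tr, X_te = X[train_idx], X[test_idx]
        if spec.standardization == "per_fold":
            X_tr, mean, scale = standardize_features(X_tr)
            X_te = (X_te - mean) / scale
        clf = SVC(kernel="linear", C=spec.box_constraint)
        clf.fit(X_tr, y_tr)
        a, b = _platt_sigmoid(clf.decision_function(X_tr), y_tr)
        d = float(clf.decision_function(X_te)[0])
        pred[test_idx] = int(clf.predict(X_te)[0])
        post[test_idx] = expit(a * d + b)
        decision[test_idx] = d
    out = pd.DataFrame(
        {"label": y, "predicted": pred, "posterior": post, "decision": decision}
    )
    if index is not None:
        out.index = index
    return out


@dataclass
class ConfusionMatrix:
    """TP/FP/TN/FN counts with the three derived rates."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.fp + self.tn)


def confusion_metrics(predictions, labels) -> ConfusionMatrix:
    """Count TP/FP/TN/FN for binary 0/1 predictions against 0/1 labels."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    if not (set(np.unique(pred)) <= {0, 1} and set(np.unique(y)) <= {0, 1}):
        raise ValueError("labels and predictions must be coded 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def confusion_from_rates(
    n_positive: int, n_negative: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Reconstruct the integer confusion matrix implied by printed rates.

    Given group sizes and reported sensitivity/specificity, the nearest
    integer counts are TP = round(sens * n+) and TN = round(spec * n-);
    useful for recovering a full matrix from a results summary.
    """
    tp = round(sensitivity * n_positive)
    tn = round(specificity * n_negative)
    return ConfusionMatrix(tp=tp, fp=n_negative - tn, tn=tn, fn=n_positive - tp)


@dataclass
class RocCurve:
    """ROC points over posterior-probability thresholds plus trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(posteriors, labels) -> RocCurve:
    """ROC curve and trapezoidal AUC from scores and 0/1 labels.

    Thresholds sweep the unique score values (plus a sentinel above the
    maximum); tied scores enter the curve at a single threshold step. The
    curve starts at (0, 0) and ends at (1, 1); AUC is the trapezoidal
    integral of TPR over FPR.
    """
    s = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # `cut` holds the last index of each tie group so tied scores share a step
    cut = np.append(np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1)
    tp_cum = np.cumsum(y_sorted == 1)[cut]
    fp_cum = np.cumsum(y_sorted == 0)[cut]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[cut]])
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=float(np.trapezoid(tpr, fpr)),
    )


@dataclass
class ConcordanceSummary:
    """Agreement between the dipole-fit (ECD) and SVM lateralization calls."""

    both_lateralized_agree: int
    svm_only: int
    ecd_only: int
    neither: int

    @property
    def total(self) -> int:
        return self.both_lateralized_agree + self.svm_only + self.ecd_only + self.neither


_UNILATERAL = {"L", "R"}


def ecd_concordance(fixture: pd.DataFrame) -> ConcordanceSummary:
    """Cross-tabulate which method lateralized each patient.

    A dipole (ECD) call is lateralizing iff it is L or R (not Bilateral or
    No spike); an SVM call is lateralizing iff it is L or R (not CTR).
    ``both_lateralized_agree`` additionally requires the two unilateral calls
    to name the same side.
    """
    allowed_ecd = _UNILATERAL | {"Bilateral", "No spike"}
    allowed_svm = _UNILATERAL | {"CTR"}
    bad = set(fixture["ecd"]) - allowed_ecd | (set(fixture["linear_svm"]) - allowed_svm)
    if bad:
        raise ValueError(f"unknown lateralization calls: {sorted(bad)}")
    ecd_lat = fixture["ecd"].isin(_UNILATERAL)
    svm_lat = fixture["linear_svm"].isin(_UNILATERAL)
    agree = ecd_lat & svm_lat & (fixture["ecd"] == fixture["linear_svm"])
    return ConcordanceSummary(
        both_lateralized_agree=int(agree.sum()),
        svm_only=int((svm_lat & ~ecd_lat).sum()),
        ecd_only=int((ecd_lat & ~svm_lat).sum()),
        # both-unilateral-but-disagreeing patients would be counted here too;
        # the study table contains none
        neither=int((~(agree | (svm_lat & ~ecd_lat) | (ecd_lat & ~svm_lat))).sum()),
    )


def run_scenario(
    X: pd.DataFrame,
    meta: pd.DataFrame,
    spec: ClassifierSpec,
    seed: int = 0,
) -> tuple[pd.DataFrame, ConfusionMatrix, RocCurve]:
    """LOOCV one scenario from the full cohort feature matrix.

    Subsets the feature matrix to the scenario's patient group plus controls,
    codes patients as the positive class, and returns (per-subject
    predictions, confusion matrix, ROC curve).
    """
    patient_group, control_group = SCENARIOS[spec.scenario]
    mask = meta["group"].isin((patient_group, control_group))
    X_s = X.loc[mask.to_numpy()]
    y = (meta.loc[mask.to_numpy(), "group"] == patient_group).astype(int)
    preds = loocv_classify(X_s, y.to_numpy(), spec, seed=seed)
    cm = confusion_metrics(preds["predicted"], preds["label"])
    roc = roc_auc(preds["posterior"].to_numpy(), preds["label"].to_numpy())
    return preds, cm, roc
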
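"""Connectome-based predictive modeling (CPM) for binary classification.

CPM is deliberately simple: features whose two-sample t-test p-value
falls below a lenient threshold (default 0.3) are split into a
positive set (mean higher in class 1) and a negative set (mean higher
in class 0); each subject's score is the sum of their positive
features minus the sum of their negative features; a scalar decision
threshold fitted on the training cohort — the accuracy-maximizing
midpoint between sorted scores — classifies new subjects.  The model
is applied to an external cohort verbatim, with no refitting.

:class:`CPMClassifier` follows the scikit-learn estimator contract
(fit/predict/decision_function, get_params/set_params, trailing
underscore fitted attributes), so it composes with sklearn pipelines
and model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from oscillome.stats import feature_ttest


def select_features(
    features: np.ndarray,
    labels: np.ndarray,
    p_threshold: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Index sets (positive, negative) of features with t-test p < threshold.

    Positive features have a higher mean in class 1 (the larger label
    under np.unique ordering), negative ones in class 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need two classes, got {classes}")
    a, b = X[y == classes[0]], X[y == classes[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = feature_ttest(a, b)
    selected = p < p_threshold
    higher_in_1 = b.mean(axis=0) > a.mean(axis=0)
    pos = np.flatnonzero(selected & higher_in_1)
    neg = np.flatnonzero(selected & ~higher_in_1)
    if pos.size == 0 and neg.size == 0:
        warnings.warn(
            "no features selected; the model scores every subject 0", stacklevel=2
        )
    return pos, neg


def score_subjects(
    features: np.ndarray,
    pos_features: np.ndarray,
    neg_features: np.ndarray,
    convention: str = "difference",
) -> np.ndarray:
    """CPM score per subject: sum(pos) - sum(neg) (or sum(pos) + sum(neg)).

    The ``difference`` convention makes both effect directions push the
    score toward class 1; ``sum`` adds the two sets with the same sign.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    pos = X[:, np.asarray(pos_features, dtype=int)].sum(axis=1) if len(pos_features) else 0.0
    neg = X[:, np.asarray(neg_features, dtype=int)].sum(axis=1) if len(neg_features) else 0.0
    if convention == "difference":
        return pos - neg
    if convention == "sum":
        return pos + neg
    raise ValueError(f"unknown score convention {convention!r}")


def fit_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Accuracy-maximizing score threshold: (threshold, training accuracy).

    Candidates are the midpoints between consecutive sorted unique
    scores plus one candidate below the minimum; classification is
    score >= threshold -> class 1.  Ties in accuracy break toward the
    midpoint of the widest gap between adjacent scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need both classes to fit a threshold")
    y1 = y == classes[1]
    uniq = np.unique(s)
    if uniq.size == 1:
        warnings.warn("constant scores; threshold set at that constant", stacklevel=2)
        thr = float(uniq[0])
        acc = max(y1.mean(), 1 - y1.mean())
        return thr, float(acc)
    mids = (uniq[:-1] + uniq[1:]) / 2
    gaps = np.diff(uniq)
    candidates = np.concatenate([[uniq[0] - 1.0], mids])
    cand_gaps = np.concatenate([[0.0], gaps])
    accs = np.array([np.mean((s >= c) == y1) for c in candidates])
    best = accs == accs.max()
    pick = np.flatnonzero(best)[np.argmax(cand_gaps[best])]
    return float(candidates[pick]), float(accs[pick])


@dataclass
class ROCResult:
    """Threshold sweep of a score-based classifier."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float


def evaluate(
    scores: np.ndarray, labels: np.ndarray, decision_threshold: float
) -> ROCResult:
    """ROC curve, rank-based AUC, and threshold metrics.

    AUC uses the Mann-Whitney formulation (tied scores count 1/2);
    sensitivity and specificity are computed at ``decision_threshold``
    with the score >= threshold -> class 1 rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need both classes to evaluate")
    y1 = y == classes[1]
    n1, n0 = int(y1.sum()), int((~y1).sum())
    ranks = sps.rankdata(s)
    auc = (ranks[y1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    sweep = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([np.mean(s[y1] >= t) for t in sweep])
    fpr = np.array([np.mean(s[~y1] >= t) for t in sweep])
    pred = s >= decision_threshold
    return ROCResult(
        thresholds=sweep,
        tpr=tpr,
        fpr=fpr,
        auc=float(auc),
        accuracy=float(np.mean(pred == y1)),
        sensitivity=float(np.mean(pred[y1])) if n1 else np.nan,
        specificity=float(np.mean(~pred[~y1])) if n0 else np.nan,
    )


class CPMClassifier(ClassifierMixin, BaseEstimator):
    """Summed-feature threshold classifier over selected connectome features.

    Parameters
    ----------
    p_threshold : float, default 0.3
        Two-sample t-test p-value cutoff for feature selection.
    score_convention : {"difference", "sum"}, default "difference"
        How positive and negative feature sums combine into the score.
    fingerprint : hashable, optional
        Feature-space identity (band, family, dimension).  External
        cohorts must present the same fingerprint to be scored.

    Attributes (after fit)
    ----------------------
    classes_, pos_features_, neg_features_, decision_threshold_,
    train_accuracy_, train_auc_, train_sensitivity_, train_specificity_
    """

    def __init__(
        self,
        p_threshold: float = 0.3,
        score_convention: str = "difference",
        fingerprint=None,
    ):
        self.p_threshold = p_threshold
        self.score_convention = score_convention
        self.fingerprint = fingerprint

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be (n_subjects, n_features) matching y")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("CPM is a binary classifier")
        self.n_features_in_ = X.shape[1]
        self.fingerprint_ = (
            self.fingerprint if self.fingerprint is not None else ("cpm", X.shape[1])
        )
        self.pos_features_, self.neg_features_ = select_features(
            X, y, self.p_threshold
        )
        scores = self.score_samples(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.decision_threshold_, self.train_accuracy_ = fit_threshold(scores, y)
        roc = evaluate(scores, y, self.decision_threshold_)
        self.train_auc_ = roc.auc
        self.train_sensitivity_ = roc.sensitivity
        self.train_specificity_ = roc.specificity
        return self

    def _check_fingerprint(self, X, fingerprint=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.n_features_in_}"
            )
        if fingerprint is not None and fingerprint != self.fingerprint_:
            raise ValueError(
                f"feature-space fingerprint mismatch: {fingerprint!r} vs "
                f"{self.fingerprint_!r}; refusing to score"
            )
        return X

    def score_samples(self, X) -> np.ndarray:
        """Raw CPM scores (before thresholding)."""
        check_is_fitted(self, "pos_features_")
        X = self._check_fingerprint(X)
        return score_subjects(
            X, self.pos_features_, self.neg_features_, self.score_convention
        )

    def decision_function(self, X) -> np.ndarray:
        return self.score_samples(X) - self.decision_threshold_

    def predict(self, X):
        check_is_fitted(self, "decision_threshold_")
        scores = self.score_samples(X)
        return np.where(
            scores >= self.decision_threshold_, self.classes_[1], self.classes_[0]
        )

    def evaluate_external(self, X, y, fingerprint=None) -> ROCResult:
        """Apply the fitted model unchanged to an external cohort."""
        check_is_fitted(self, "decision_threshold_")
        X = self._check_fingerprint(X, fingerprint)
        scores = score_subjects(
            X, self.pos_features_, self.neg_features_, self.score_convention
        )
        return evaluate(scores, y, self.decision_threshold_)


def apply_external(
    model: CPMClassifier, features: np.ndarray, labels: np.ndarray, fingerprint=None
) -> ROCResult:
    """Module-level wrapper over :meth:`CPMClassifier.evaluate_external`."""
    return model.evaluate_external(features, labels, fingerprint=fingerprint)


def threshold_sweep(
    train_X, train_y, test_X, test_y, p_thresholds=(0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
) -> "list[dict]":
    """Refit the CPM at several selection thresholds; report AUCs per threshold."""
    out = []
    for p in p_thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = CPMClassifier(p_threshold=p).fit(train_X, train_y)
            ext = model.evaluate_external(test_X, test_y)
        out.append(
            {
                "p_threshold": p,
                "n_selected": len(model.pos_features_) + len(model.neg_features_),
                "train_auc": model.train_auc_,
                "test_auc": ext.auc,
            }
        )
    return out
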
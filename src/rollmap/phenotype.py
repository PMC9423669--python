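"""Phenotype prediction from per-mouse patch-class proportions.

Linear discriminant analysis (shared-covariance Gaussian classifier, with
Ledoit-Wolf covariance shrinkage because compositional features over few
mice can make the pooled covariance singular) predicts (a) the mouse model
and (b) the clinical-score bin from the proportion features.  The clinical
score (0-12 composite of weight loss, stool consistency and fecal blood)
is binned Low = 0-2, Mid = 3-7, High = 8-12.  The per-slide
InvolvedProportion is additionally correlated with raw clinical score via
the squared Pearson coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.utils.validation import check_is_fitted

SCORE_BINS = (("Low", 0, 2), ("Mid", 3, 7), ("High", 8, 12))


def bin_score(score: int) -> str:
    """Map a 0-12 clinical score to its bin name."""
    if not 0 <= score <= 12 or int(score) != score:
        raise ValueError(f"clinical score must be an integer in [0, 12], got {score}")
    for name, lo, hi in SCORE_BINS:
        if lo <= score <= hi:
            return name
    raise AssertionError("unreachable: bins partition 0-12")


class PhenotypeLDA(ClassifierMixin, BaseEstimator):
    """LDA on proportion features with empirical priors and shrinkage.

    ``shrinkage='auto'`` uses Ledoit-Wolf estimation; pass a float in
    [0, 1] for fixed shrinkage or ``None`` for the unshrunk estimator.
    """

    def __init__(self, shrinkage="auto"):
        self.shrinkage = shrinkage

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need >= 2 classes to fit LDA")
        small = classes[counts < 2]
        if small.size:
            raise ValueError(f"classes with < 2 samples: {small.tolist()}")
        self.lda_ = LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=self.shrinkage).fit(X, y)
        self.classes_ = self.lda_.classes_
        self.means_ = self.lda_.means_
        self.priors_ = self.lda_.priors_
        self.covariance_ = self.lda_.covariance_
        self.n_features_in_ = X.shape[1]
        return self

    def _check_width(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[-1]} != model width {self.n_features_in_}")
        return X

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self._check_width(X))

    def predict_proba(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict_proba(self._check_width(X))


def train_lda(features, labels, shrinkage="auto") -> PhenotypeLDA:
    return PhenotypeLDA(shrinkage=shrinkage).fit(features, labels)


def predict_lda(model: PhenotypeLDA, features) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-class posterior probabilities."""
    return model.predict(features), model.predict_proba(features)


def correlate_involvement(proportions, scores) -> float:
    """Squared Pearson correlation between InvolvedProportion and score."""
    p = np.asarray(proportions, dtype=np.float64)
    s = np.asarray(scores, dtype=np.float64)
    if p.size != s.size or p.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(p) == 0 or np.var(s) == 0:
        raise ValueError("zero variance in proportions or scores")
    r = stats.pearsonr(p, s).statistic
    return float(r * r)


def evaluate_phenotype(predictions, truths) -> dict:
    """Confusion matrix (rows = truth), accuracy and weighted F1."""
    pred = np.asarray(predictions)
    truth = np.asarray(truths)
    if pred.size != truth.size:
        raise ValueError("predictions and truths must have equal length")
    if truth.size == 0:
        raise ValueError("empty evaluation input")
    if not set(pred) <= set(truth):
        raise ValueError(
            f"prediction labels {sorted(set(pred) - set(truth))} absent from truth")
    labels = sorted(set(truth))
    cm = confusion_matrix(truth, pred, labels=labels)
    return {
        "labels": labels,
        "confusion": cm,
        "accuracy": float(np.trace(cm) / cm.sum()),
        "weighted_f1": float(f1_score(truth, pred, labels=labels,
                                      average="weighted", zero_division=0)),
    }


def proportion_table(features: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join proportion features with mouse metadata (model, clinical score)."""
    meta = metadata.set_index("mouse_id")[["model", "clinical_score"]]
    return features.join(meta, how="inner")
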
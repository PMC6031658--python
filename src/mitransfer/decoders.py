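"""LDA classification and the per-subject bagging ensemble.

The discriminant is the pooled-covariance linear discriminant (equal class
priors, matching the balanced 40/40 design), with Ledoit-Wolf shrinkage of
the pooled covariance when it is ill-conditioned.  Class probabilities are
the logistic of the discriminant score; an exact 0.5 resolves to class -1
(right hand) by convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .spectral import FeatureMatrix

log = logging.getLogger(__name__)

_COND_MAX = 1e8


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    class_means: np.ndarray  # rows: class -1, class +1

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != len(self.weights):
            raise ValueError(f"feature dimension {X.shape[1]} does not match "
                             f"model dimension {len(self.weights)}")
        return X @ self.weights + self.bias


@dataclass
class BaggedEnsemble:
    members: list  # (subject_id, LDAModel)
    aggregation: str = "mean_probability"  # or "majority"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.aggregation not in ("mean_probability", "majority"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


def _unpack(features, labels):
    if isinstance(features, FeatureMatrix):
        return features.values, features.labels
    return np.asarray(features, float), np.asarray(labels)


def fit_lda(features, labels=None) -> LDAModel:
    """Pooled-covariance LDA with equal priors; shrinkage is engaged only
    when the pooled within-class covariance is ill-conditioned."""
    X, y = _unpack(features, labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("LDA requires both classes in the training labels")
    if X.shape[0] <= 2:
        raise ValueError("need more than 2 training samples")

    centered = np.concatenate([X[y == c] - X[y == c].mean(axis=0)
                               for c in classes])
    pooled = np.cov(centered, rowvar=False)
    pooled = np.atleast_2d(pooled)
    cond = np.linalg.cond(pooled)
    shrinkage = None
    if not np.isfinite(cond) or cond > _COND_MAX:
        shrinkage = "auto"
        log.info("pooled covariance ill-conditioned (cond=%.3g); "
                 "Ledoit-Wolf shrinkage enabled", cond)
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                     priors=[0.5, 0.5])
    clf.fit(X, y)
    # orient so that positive score means class +1 (clf.classes_ is sorted)
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    return LDAModel(weights=w, bias=b, class_means=means)


def predict_lda(model: LDAModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class +1 probabilities.

    Probability is the logistic of the discriminant score; the label is +1
    iff that probability strictly exceeds 0.5 (score > 0), so an exact tie
    resolves to -1."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    s = model.scores(X)
    prob = expit(s)
    labels = np.where(s > 0, 1, -1)
    return labels, prob


def bagged_predict(ensemble: BaggedEnsemble, features) -> np.ndarray:
    """Aggregate member predictions over the per-subject LDA ensemble."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    probs = np.stack([predict_lda(m, X)[1] for _, m in ensemble.members])
    if ensemble.aggregation == "mean_probability":
        return np.where(probs.mean(axis=0) > 0.5, 1, -1)
    votes = np.where(probs > 0.5, 1, -1).sum(axis=0)
    return np.where(votes > 0, 1, -1)
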
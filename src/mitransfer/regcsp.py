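"""Cross-subject regularized CSP.

The subject-specific class covariances are shrunk toward *generic* class
covariances pooled over the training subjects, each weighted by the inverse
squared Frobenius distance between that training subject's (label-free)
covariance and the test subject's covariance:

    G_c = (1/N) sum_i (1/fn_i) C_c^i,   fn_i = sum_jk (C_test - C_train_i)_jk^2

The regularized covariances are

    C_hat_c   = (1 - beta) C_c + beta G_c
    C_tilde_c = (1 - gamma) C_hat_c + gamma I

and CSP filters maximize  w' C_tilde_1 w / w' C_tilde_2 w.  The identity
term is added by default (positive-definite shrinkage); the subtractive
variant is available via ``identity_sign="minus"`` with an eigenvalue floor.
beta and gamma are tuned on an 11 x 11 grid by splitting the training
subjects into an optimization half (leave-one-out scored) and a training
half.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import decoders
from .spectral import (SpatialFilterModel, SpectralBand, butter_band,
                       csp_from_covariances, epoch_covariances,
                       mean_covariance)
from .synthetic import EpochSet

log = logging.getLogger(__name__)

GRID_STEP = 0.1
_WEIGHT_CAP = 1e12


@dataclass(frozen=True)
class RegCSPParams:
    beta: float
    gamma: float
    grid_step: float = GRID_STEP
    identity_sign: str = "plus"  # "plus" (default) or "minus"

    def __post_init__(self) -> None:
        for name in ("beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
            k = v / self.grid_step
            if abs(k - round(k)) > 1e-9:
                raise ValueError(f"{name}={v} is not on the "
                                 f"{self.grid_step}-spaced grid")
        if self.identity_sign not in ("plus", "minus"):
            raise ValueError("identity_sign must be 'plus' or 'minus'")


@dataclass
class SubjectCovariances:
    """Per-subject class covariances plus the label-free pooled covariance."""

    subject_id: int
    C_pos: np.ndarray  # class +1 (left hand)
    C_neg: np.ndarray  # class -1 (right hand)
    pooled: np.ndarray  # all epochs, no label information


@dataclass
class GenericCovariance:
    G_pos: np.ndarray
    G_neg: np.ndarray
    weights: np.ndarray  # per training subject, 1/fn
    n_subjects: int
    subject_ids: list = field(default_factory=list)


def subject_class_covariances(epochs: EpochSet) -> SubjectCovariances:
    """Trace-normalized average epoch covariances per class and pooled."""
    labels = np.asarray(epochs.labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes required to form class covariances")
    c_pos = mean_covariance(epochs.data[labels > 0])
    c_neg = mean_covariance(epochs.data[labels <= 0])
    pooled = mean_covariance(epochs.data)
    return SubjectCovariances(subject_id=epochs.subject_id,
                              C_pos=c_pos, C_neg=c_neg, pooled=pooled)


def frobenius_weight(test_pooled: np.ndarray, train_pooled: np.ndarray,
                     squared: bool = True) -> float:
    """1 / fn with fn the (squared) Frobenius distance between the test
    subject's and a training subject's label-free covariance."""
    fn = float(np.sum((test_pooled - train_pooled) ** 2))
    if not squared:
        fn = np.sqrt(fn)
    if fn == 0.0:
        log.info("identical covariances (fn = 0); capping weight at %.1e",
                 _WEIGHT_CAP)
        return _WEIGHT_CAP
    return min(1.0 / fn, _WEIGHT_CAP)


def generic_covariance(train_covs: list[SubjectCovariances],
                       test_pooled: np.ndarray,
                       weighting: str = "frobenius_inverse_square",
                       squared: bool = True) -> GenericCovariance:
    """Weighted cross-subject covariance pool G_c = (1/N) sum_i (1/fn_i) C_c^i.

    The weights use only the test subject's label-free covariance, so no
    test-subject labels enter training."""
    if not train_covs:
        raise ValueError("need at least one training subject")
    if weighting == "uniform":
        w = np.ones(len(train_covs))
    elif weighting == "frobenius_inverse_square":
        w = np.array([frobenius_weight(test_pooled, tc.pooled, squared)
                      for tc in train_covs])
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    n = len(train_covs)
    G_pos = sum(wi * tc.C_pos for wi, tc in zip(w, train_covs)) / n
    G_neg = sum(wi * tc.C_neg for wi, tc in zip(w, train_covs)) / n
    return GenericCovariance(G_pos=G_pos, G_neg=G_neg, weights=w, n_subjects=n,
                             subject_ids=[tc.subject_id for tc in train_covs])


def fit_regcsp(C_pos: np.ndarray, C_neg: np.ndarray,
               generic: GenericCovariance, params: RegCSPParams,
               n_components: int = 10) -> SpatialFilterModel:
    """Regularized CSP filters from a subject-level covariance pair and the
    generic covariances."""
    b, g = params.beta, params.gamma
    eye = np.eye(C_pos.shape[0])
    sign = 1.0 if params.identity_sign == "plus" else -1.0
    C1 = (1 - g) * ((1 - b) * C_pos + b * generic.G_pos) + sign * g * eye
    C2 = (1 - g) * ((1 - b) * C_neg + b * generic.G_neg) + sign * g * eye
    model = csp_from_covariances(C1, C2, n_components)
    model.kind = "CSP"
    return model


@dataclass
class RegCspSubject:
    """A training subject prepared for regularized CSP: per-epoch raw
    covariances of the band-filtered epochs plus the derived class
    covariances.  Log-power features of a projection W are
    log diag(W' C_e W), so the raw epochs are not needed again."""

    covs: SubjectCovariances
    epoch_covs: np.ndarray  # epochs x channels x channels, unnormalized
    labels: np.ndarray

    @property
    def subject_id(self) -> int:
        return self.covs.subject_id


def prepare_regcsp_subject(epochs: EpochSet, band: SpectralBand) -> RegCspSubject:
    data = butter_band(epochs.data, band.lo, band.hi, epochs.sfreq)
    filtered = epochs.copy_with(data=data)
    return RegCspSubject(covs=subject_class_covariances(filtered),
                         epoch_covs=epoch_covariances(data, trace_norm=False),
                         labels=np.asarray(epochs.labels))


def _logpower_from_covs(epoch_covs: np.ndarray, W: np.ndarray) -> np.ndarray:
    power = np.einsum("dk,edf,fk->ek", W, epoch_covs, W)
    return np.log(np.maximum(power, 1e-300))


def split_halves(subjects: list[RegCspSubject]):
    """Deterministic optimization/training split: subjects sorted by id;
    even positions form the optimization half, odd the training half."""
    ordered = sorted(subjects, key=lambda s: s.subject_id)
    return ordered[0::2], ordered[1::2]


def _mean_class_covs(subjects: list[RegCspSubject]):
    C_pos = np.mean([s.covs.C_pos for s in subjects], axis=0)
    C_neg = np.mean([s.covs.C_neg for s in subjects], axis=0)
    return C_pos, C_neg


def _fit_eval(train_half: list[RegCspSubject], test_pooled: np.ndarray,
              params: RegCSPParams, n_components: int):
    """Fit RCSP filters + LDA on the training half, targeting a given test
    covariance; return (model, lda)."""
    gen = generic_covariance([s.covs for s in train_half], test_pooled)
    C_pos, C_neg = _mean_class_covs(train_half)
    model = fit_regcsp(C_pos, C_neg, gen, params, n_components)
    feats = np.vstack([_logpower_from_covs(s.epoch_covs, model.filters)
                       for s in train_half])
    labels = np.concatenate([s.labels for s in train_half])
    lda = decoders.fit_lda(feats, labels)
    return model, lda


def _score(model, lda, subject: RegCspSubject) -> float:
    feats = _logpower_from_covs(subject.epoch_covs, model.filters)
    pred, _ = decoders.predict_lda(lda, feats)
    return float(np.mean(pred == subject.labels))


def tune_regcsp(subjects: list[RegCspSubject], n_components: int = 10,
                grid_step: float = GRID_STEP,
                identity_sign: str = "plus") -> RegCSPParams:
    """Select (beta, gamma) on the regular grid by leave-one-out accuracy
    over the optimization half, trained on the training half.  Ties resolve
    toward smaller (beta, gamma) in lexicographic order."""
    if len(subjects) < 4:
        raise ValueError("tuning requires at least 4 training subjects")
    opt_half, train_half = split_halves(subjects)
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    best, best_acc = None, -np.inf
    for b, g in itertools.product(grid, grid):
        params = RegCSPParams(beta=float(b), gamma=float(g),
                              grid_step=grid_step, identity_sign=identity_sign)
        accs = []
        for held in opt_half:
            model, lda = _fit_eval(train_half, held.covs.pooled, params,
                                   n_components)
            accs.append(_score(model, lda, held))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:  # strict: earlier (smaller) grid point wins ties
            best, best_acc = params, acc
    return best


def regcsp_train_predict(train_subjects: list[RegCspSubject],
                         test_epochs: EpochSet, band: SpectralBand,
                         n_components: int = 10,
                         params: RegCSPParams | None = None) -> np.ndarray:
    """Full RCSP decoder for one leave-one-subject-out fold: tune (beta,
    gamma) on the training subjects, then fit on the training half using the
    test subject's label-free covariance for the generic weighting, and
    predict the test subject's epochs."""
    if params is None:
        params = tune_regcsp(train_subjects, n_components)
    test_data = butter_band(test_epochs.data, band.lo, band.hi, test_epochs.sfreq)
    test_covs = epoch_covariances(test_data, trace_norm=False)
    test_pooled = mean_covariance(test_data)
    _, train_half = split_halves(train_subjects)
    model, lda = _fit_eval(train_half, test_pooled, params, n_components)
    feats = _logpower_from_covs(test_covs, model.filters)
    pred, _ = decoders.predict_lda(lda, feats)
    return pred
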
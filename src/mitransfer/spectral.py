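"""Spectral band selection, SSD and CSP spatial filtering, and log-power
features: the front end shared by all CSP-based decoders.

SSD (spatio-spectral decomposition) finds projections maximizing power in a
narrow band of interest against its flanking bands; CSP (common spatial
patterns) finds projections maximizing the variance of one class against the
total.  Both are generalized symmetric eigenproblems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .synthetic import EpochSet

log = logging.getLogger(__name__)

DEFAULT_BAND_CENTER = 10.0
DEFAULT_HALF_WIDTH = 3.0
FLANK_WIDTH = 2.0  # width of each SSD flanking band (Hz)


@dataclass(frozen=True)
class SpectralBand:
    center: float
    half_width: float = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if self.center - self.half_width <= 0:
            raise ValueError("band must lie above 0 Hz")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass
class SpatialFilterModel:
    kind: str  # "SSD" or "CSP"
    filters: np.ndarray  # input-dim x components
    patterns: np.ndarray  # input-dim x components
    eigenvalues: np.ndarray
    n_components: int
    band: SpectralBand | None = None

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project (epochs x dim x samples) to (epochs x components x samples)."""
        return np.einsum("dk,eds->eks", self.filters, data)


@dataclass
class FeatureMatrix:
    values: np.ndarray  # samples x features
    labels: np.ndarray
    subject_id: int | None = None
    feature_kind: str = "csp_logpower"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels not aligned with feature rows")


def butter_band(data: np.ndarray, lo: float, hi: float, sfreq: float,
                order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def _post_cue(epochs: EpochSet) -> np.ndarray:
    mask = epochs.times >= 0.0
    return epochs.data[..., mask] if mask.any() else epochs.data


def select_band(rest: EpochSet, active: EpochSet,
                half_width: float = DEFAULT_HALF_WIDTH) -> SpectralBand:
    """Frequency band with the strongest task-related power decrease.

    The relative power decrease (rest - active) / rest, averaged over
    channels, is evaluated in 1-Hz bins over 8-30 Hz; the band of interest is
    the winning bin's center +/- `half_width`.  If no bin shows a decrease,
    the conventional 10 +/- 3 Hz sensorimotor band is returned with a warning.
    """
    if rest.sfreq != active.sfreq or rest.n_channels != active.n_channels:
        raise ValueError("rest and active sets must share sfreq and channels")
    sfreq = rest.sfreq

    def mean_psd(x):
        nper = min(x.shape[-1], int(round(sfreq)))
        f, p = signal.welch(x, fs=sfreq, nperseg=nper, axis=-1)
        return f, p.mean(axis=(0, 1))

    f_r, p_rest = mean_psd(_post_cue(rest))
    f_a, p_act = mean_psd(_post_cue(active))
    assert np.allclose(f_r, f_a)
    decrease = (p_rest - p_act) / np.maximum(p_rest, 1e-300)
    centers = np.arange(8, 31, dtype=float)
    dec_at = np.interp(centers, f_r, decrease)
    if dec_at.max() <= 0:
        log.warning("no power decrease in 8-30 Hz; falling back to the "
                    "default 10 +/- 3 Hz band")
        return SpectralBand(DEFAULT_BAND_CENTER, half_width)
    return SpectralBand(float(centers[np.argmax(dec_at)]), half_width)


def epoch_covariances(data: np.ndarray, trace_norm: bool = True) -> np.ndarray:
    """Per-epoch sample covariance (dim x dim), optionally trace-normalized."""
    n_t = data.shape[-1]
    covs = np.einsum("eds,efs->edf", data, data) / n_t
    if trace_norm:
        tr = np.trace(covs, axis1=1, axis2=2)
        covs = covs / np.maximum(tr, 1e-300)[:, None, None]
    return covs


def mean_covariance(data: np.ndarray, trace_norm: bool = True) -> np.ndarray:
    return epoch_covariances(data, trace_norm).mean(axis=0)


def _shrink_if_needed(C: np.ndarray, cond_max: float = 1e10) -> np.ndarray:
    """Regularize a rank-deficient, ill-conditioned or indefinite matrix by
    an identity shift that floors its spectrum at a small positive value
    (logged)."""
    w = np.linalg.eigvalsh(C)
    eps = max(w[-1], 1e-300) / cond_max
    if w[0] < eps:
        log.info("matrix spectrum floored at %.3g (min eigenvalue %.3g)", eps, w[0])
        return C + (eps - w[0]) * np.eye(C.shape[0])
    return C


def _patterns_from_filters(W: np.ndarray) -> np.ndarray:
    """Activation patterns = pseudoinverse-transpose of the filter matrix."""
    return np.linalg.pinv(W).T


def ssd_from_covariances(S: np.ndarray, N: np.ndarray, n_keep: int,
                         band: SpectralBand | None = None) -> SpatialFilterModel:
    """SSD filters from a signal-band and flanking-band covariance pair."""
    if n_keep > S.shape[0]:
        raise ValueError("n_keep exceeds input dimension")
    N = _shrink_if_needed(N)
    evals, evecs = linalg.eigh(S, N)
    order = np.argsort(evals)[::-1][:n_keep]
    W = evecs[:, order]
    return SpatialFilterModel(kind="SSD", filters=W,
                              patterns=_patterns_from_filters(W),
                              eigenvalues=evals[order], n_components=n_keep,
                              band=band)


def ssd_covariances(data: np.ndarray, band: SpectralBand,
                    sfreq: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean covariances of the signal band and of the two flanking bands."""
    x_sig = butter_band(data, band.lo, band.hi, sfreq)
    x_lo = butter_band(data, max(band.lo - FLANK_WIDTH, 0.5), band.lo, sfreq)
    x_hi = butter_band(data, band.hi, band.hi + FLANK_WIDTH, sfreq)
    S = mean_covariance(x_sig, trace_norm=False)
    N = mean_covariance(x_lo, trace_norm=False) + \
        mean_covariance(x_hi, trace_norm=False)
    return S, N


def fit_ssd(epochs: EpochSet, band: SpectralBand, n_keep: int) -> SpatialFilterModel:
    """Spatio-spectral decomposition: maximize power in `band` against the
    two flanking bands [lo - 2, lo] and [hi, hi + 2] Hz."""
    if n_keep > epochs.n_channels:
        raise ValueError("n_keep exceeds channel count")
    S, N = ssd_covariances(epochs.data, band, epochs.sfreq)
    return ssd_from_covariances(S, N, n_keep, band)


def fit_csp(data: np.ndarray | EpochSet, labels: np.ndarray | None = None,
            n_components: int = 10) -> SpatialFilterModel:
    """Two-class CSP via the generalized eigenproblem C1 w = lambda (C1+C2) w.

    Half the components are taken from each end of the eigenvalue spectrum
    and ordered by decreasing eigenvalue (class +1 variance fraction).
    The returned filters W satisfy W.T (C1+C2) W = I."""
    if isinstance(data, EpochSet):
        labels = data.labels if labels is None else labels
        data = data.data
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("CSP requires exactly two classes in the labels")
    if n_components % 2 or n_components > data.shape[1]:
        raise ValueError("n_components must be even and <= input dimension")
    covs = epoch_covariances(data, trace_norm=True)
    # class +1 is the numerator class by the sign convention (+1 = left hand)
    c_pos = classes.max()
    C1 = covs[labels == c_pos].mean(axis=0)
    C2 = covs[labels != c_pos].mean(axis=0)
    return csp_from_covariances(C1, C2, n_components)


def csp_from_covariances(C1: np.ndarray, C2: np.ndarray,
                         n_components: int) -> SpatialFilterModel:
    """CSP filter selection from a pair of class covariances."""
    total = _shrink_if_needed(C1 + C2)
    evals, evecs = linalg.eigh(C1, total)
    half = n_components // 2
    order = np.argsort(evals)[::-1]
    sel = np.concatenate([order[:half], order[-half:]])
    sel = sel[np.argsort(evals[sel])[::-1]]  # descending eigenvalue
    W = evecs[:, sel]
    return SpatialFilterModel(kind="CSP", filters=W,
                              patterns=_patterns_from_filters(W),
                              eigenvalues=evals[sel], n_components=n_components)


def csp_logpower_features(data: np.ndarray | EpochSet,
                          ssd: SpatialFilterModel | None,
                          csp: SpatialFilterModel,
                          labels: np.ndarray | None = None,
                          subject_id: int | None = None) -> FeatureMatrix:
    """Project epochs through SSD then CSP and take the log of the
    time-averaged component power (log-variance), one row per epoch."""
    if isinstance(data, EpochSet):
        labels = data.labels if labels is None else labels
        subject_id = data.subject_id if subject_id is None else subject_id
        data = data.data
    z = data if ssd is None else ssd.transform(data)
    z = csp.transform(z)
    power = np.mean(z ** 2, axis=-1)
    if (power <= 0).any():
        log.info("zero-power component encountered; applying numerical floor")
    feats = np.log(np.maximum(power, 1e-300))
    if labels is None:
        labels = np.zeros(feats.shape[0], int)
    return FeatureMatrix(values=feats, labels=np.asarray(labels),
                         subject_id=subject_id, feature_kind="csp_logpower")
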
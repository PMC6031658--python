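"""Offline preprocessing chain: band-pass filtering, epoch cropping with
baseline correction, common-average reference (EEG), and decimation.

The band-pass is a zero-phase FFT-domain FIR filter whose length equals the
epoch length; decimation is plain strided selection (the data are already
low-passed well below the decimated Nyquist at study scale)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import ConfigError, EpochSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocConfig:
    band: tuple[float, float] = (6.0, 45.0)
    epoch_window: tuple[float, float] = (-1.0, 2.0)
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    decimation_factor: int = 10
    reference: str = "common_average"  # or "none"

    def __post_init__(self) -> None:
        if not self.band[0] < self.band[1]:
            raise ConfigError("band low edge must be below high edge")
        if not (self.epoch_window[0] <= self.baseline_window[0]
                and self.baseline_window[1] <= self.epoch_window[1]):
            raise ConfigError("baseline_window must lie within epoch_window")
        if self.decimation_factor < 1:
            raise ConfigError("decimation_factor must be >= 1")
        if self.reference not in ("common_average", "none"):
            raise ConfigError(f"unknown reference {self.reference!r}")


def bandpass(epochs: EpochSet, band: tuple[float, float]) -> EpochSet:
    """Zero-phase FFT-domain FIR band-pass, filter length = epoch length."""
    lo, hi = band
    if hi >= epochs.sfreq / 2:
        raise ConfigError(f"band edge {hi} Hz at or above Nyquist "
                          f"({epochs.sfreq / 2} Hz)")
    n = epochs.n_samples
    numtaps = n - (1 - n % 2)  # largest odd length <= epoch length
    h = signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=epochs.sfreq)
    # apply only the amplitude response -> exactly zero phase
    amp = np.abs(np.fft.rfft(h, n))
    data = np.fft.irfft(np.fft.rfft(epochs.data, axis=-1) * amp, n=n, axis=-1)
    return epochs.copy_with(data=data)


def crop_baseline(epochs: EpochSet,
                  window: tuple[float, float] = (-1.0, 2.0),
                  baseline: tuple[float, float] = (-1.0, 0.0)) -> EpochSet:
    """Crop epochs to `window` and subtract the per-channel mean over
    `baseline` from the whole epoch."""
    times = epochs.times
    eps = 0.5 / epochs.sfreq  # half-sample tolerance against float round-off
    if window[0] < times[0] - eps or window[1] > times[-1] + 1.0 / epochs.sfreq + eps:
        raise ConfigError("crop window lies outside the recorded span")
    keep = (times >= window[0] - eps) & (times < window[1] - eps)
    data = epochs.data[..., keep]
    t_kept = times[keep]
    base = (t_kept >= baseline[0] - eps) & (t_kept < baseline[1] - eps)
    if not base.any():
        raise ConfigError("baseline window contains no samples")
    data = data - data[..., base].mean(axis=-1, keepdims=True)
    return epochs.copy_with(data=data, t0=float(t_kept[0]))


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean across channels (EEG only).

    For MEG input this is a documented no-op with a warning: the reference
    is an electrode-montage concept."""
    if epochs.modality != "EEG":
        warnings.warn("common_average_reference applied to non-EEG data; no-op",
                      stacklevel=2)
        return epochs.copy_with(data=epochs.data.copy())
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def decimate(epochs: EpochSet, factor: int) -> EpochSet:
    """Keep every `factor`-th sample starting at the first one."""
    if factor < 1:
        raise ConfigError("decimation factor must be >= 1")
    if factor > epochs.n_samples:
        raise ConfigError("decimation factor exceeds epoch length")
    if factor == 1:
        return epochs.copy_with(data=epochs.data.copy())
    return epochs.copy_with(data=epochs.data[..., ::factor].copy(),
                            sfreq=epochs.sfreq / factor)


def preprocess(epochs: EpochSet, cfg: PreprocConfig) -> EpochSet:
    """Full chain: band-pass -> crop/baseline -> reference (EEG).

    Decimation is not part of the common chain; it is applied only where the
    flattened-time-course features are built."""
    out = bandpass(epochs, cfg.band)
    out = crop_baseline(out, cfg.epoch_window, cfg.baseline_window)
    if cfg.reference == "common_average" and epochs.modality == "EEG":
        out = common_average_reference(out)
    return out
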
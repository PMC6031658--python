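"""Synthetic multi-subject MEG/EEG epoch pools with sensorimotor-rhythm structure.

The generator emulates the statistical structure that left- vs right-hand
motor-imagery (MI) decoding relies on: narrow-band mu (~10 Hz) and beta
(~20 Hz) sources in each hemisphere, mixed to sensors through smooth,
subject-specific spatial patterns, on top of 1/f background activity and
white sensor noise.  After the cue (t >= 0) the band-limited amplitude of
the source contralateral to the moving/imagined hand is multiplicatively
suppressed (event-related desynchronization, ERD); the suppression depth
and its lateralization are condition-dependent, which is what makes
passive-movement (PM) training a degraded stand-in for MI training.

Each source also carries a small cue-locked (phase-locked) burst at its
rhythm frequency, subject to the same ERD gain.  Because the burst is
phase-consistent over epochs, the class-dependent ERD lateralization leaves
a linearly decodable signature in the epoch *time courses* themselves —
the component that pooled/multi-task logistic regression on decimated
epochs exploits — while the induced (random-phase) rhythm carries the
variance signature that CSP-type decoders exploit.  With zero ERD depth
both signatures vanish and the classes are exchangeable.

Subjects differ in their spatial mixing (pattern jitter), in overall rhythm
power, in evoked phase/latency, and in "performer quality": a fraction
scaling the ERD depth, used to emulate participants with weak
sensorimotor-rhythm modulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

CONDITIONS = ("MI", "PM", "rest")
_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}

# width of each narrow-band source around its center frequency (Hz)
_SOURCE_HALF_BW = 1.5
# duration of the raised-cosine onset ramp of the ERD gain (s)
_ERD_RAMP = 0.15


class ConfigError(ValueError):
    """Invalid simulation or preprocessing configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 18 subjects, 80 epochs/condition (40 per class),
    3-s epochs (-1..2 s around the cue) at 1 kHz, 64 MEG-like channels."""

    n_subjects: int = 18
    n_channels: int = 64
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-1.0, 2.0)
    n_epochs_per_condition: int = 80
    class_balance: float = 0.5
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    erd_depth_mi: float = 0.8
    erd_depth_pm: float = 0.5
    lateralization_mi: float = 0.9
    lateralization_pm: float = 0.3
    pattern_jitter: float = 0.3
    sensor_noise_sd: float = 1.0
    background_sd: float = 1.5
    background_exponent: float = 1.0
    mu_amplitude: float = 2.2
    beta_amplitude: float = 1.1
    evoked_amplitude: float = 3.0  # cue-locked burst, relative to source sd
    evoked_latency: float = 0.30  # burst peak time after the cue (s)
    evoked_width: float = 0.20  # Gaussian envelope sd (s)
    evoked_phase_jitter: float = 0.15  # per-subject phase spread (rad)
    evoked_latency_jitter: float = 0.015  # per-subject lognormal sigma
    n_low_quality: int = 5
    quality_range: tuple[float, float] = (0.7, 1.0)
    low_quality_range: tuple[float, float] = (0.05, 0.35)
    modality: str = "MEG"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("class_balance", "erd_depth_mi", "erd_depth_pm",
                     "lateralization_mi", "lateralization_pm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        if self.sfreq <= 2 * (self.beta_freq + _SOURCE_HALF_BW):
            raise ConfigError("sfreq must exceed twice the highest source band edge")
        lo, hi = self.epoch_window
        if not (lo < 0.0 < hi):
            raise ConfigError("epoch_window must straddle the cue at t=0")
        if self.n_subjects < 1 or self.n_channels < 2:
            raise ConfigError("need at least 1 subject and 2 channels")
        if not 0 <= self.n_low_quality <= self.n_subjects:
            raise ConfigError("n_low_quality must be within [0, n_subjects]")
        if self.modality not in ("MEG", "EEG"):
            raise ConfigError(f"unknown modality {self.modality!r}")
        if self.n_epochs_per_condition < 2:
            raise ConfigError("need at least 2 epochs per condition")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq))

    def erd_depth(self, condition: str) -> float:
        return {"MI": self.erd_depth_mi, "PM": self.erd_depth_pm, "rest": 0.0}[condition]

    def lateralization(self, condition: str) -> float:
        return {"MI": self.lateralization_mi, "PM": self.lateralization_pm,
                "rest": 0.0}[condition]


@dataclass(frozen=True)
class SubjectProfile:
    """Frozen per-subject parameters shared by all of that subject's conditions."""

    subject_id: int
    mixing_matrix: np.ndarray  # channels x 4 sources, unit-norm columns
    source_band_powers: np.ndarray  # per-source amplitude (signal units)
    erd_gains: dict  # condition -> ERD depth after quality scaling
    performer_quality: float
    low_quality: bool = False
    evoked_phases: np.ndarray | None = None  # per-source burst phase (rad)
    evoked_latency: float = 0.30

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.mixing_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("mixing_matrix columns must have unit norm")


@dataclass
class EpochSet:
    """One subject/condition block of epoched multichannel signals."""

    data: np.ndarray  # epochs x channels x samples
    labels: np.ndarray  # +1 left hand, -1 right hand
    condition: str
    modality: str
    subject_id: int
    sfreq: float
    t0: float  # time of the first sample relative to the cue (s)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal epoch count")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in epoch data")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition in ("MI", "PM") and len(np.unique(self.labels)) < 2:
            raise ValueError("MI/PM epoch sets must contain both classes")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def copy_with(self, **kw) -> "EpochSet":
        return dataclasses.replace(self, **kw)


def _rng(cfg: SimConfig, *spawn_key: int) -> np.random.Generator:
    """Counter-based stream derivation: every consumer gets an independent,
    reproducible stream from the master seed and an integer spawn key."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=spawn_key))


def _base_patterns(n_channels: int) -> np.ndarray:
    """Four smooth bump patterns: mu-left, mu-right, beta-left, beta-right.

    'Left'/'right' refer to hemispheres laid out over the first/second half
    of the channel roster; the montage is a 1-D abstraction of the sensor
    sheet, sufficient for spatial-filter estimation."""
    idx = np.arange(n_channels)
    centers = np.array([0.28, 0.72, 0.33, 0.67]) * (n_channels - 1)
    width = max(2.0, 0.10 * n_channels)
    pats = np.exp(-0.5 * ((idx[:, None] - centers[None, :]) / width) ** 2)
    return pats


def make_profiles(cfg: SimConfig) -> list[SubjectProfile]:
    """Draw one SubjectProfile per subject; `cfg.n_low_quality` subjects are
    flagged as poor performers (reduced ERD gain), chosen at random."""
    rng = _rng(cfg, 0)
    base = _base_patterns(cfg.n_channels)
    low_ids = set(rng.choice(cfg.n_subjects, size=cfg.n_low_quality, replace=False))
    profiles = []
    for i in range(cfg.n_subjects):
        jitter = rng.standard_normal(base.shape)
        jitter = gaussian_filter1d(jitter, sigma=max(1.0, 0.04 * cfg.n_channels), axis=0)
        jitter /= max(np.linalg.norm(jitter, axis=0).max(), 1e-12)
        mixing = base + cfg.pattern_jitter * jitter * np.linalg.norm(base, axis=0)
        mixing = mixing / np.linalg.norm(mixing, axis=0, keepdims=True)
        amp_scale = rng.lognormal(mean=0.0, sigma=0.15, size=2)
        powers = np.array([cfg.mu_amplitude * amp_scale[0],
                           cfg.mu_amplitude * amp_scale[0],
                           cfg.beta_amplitude * amp_scale[1],
                           cfg.beta_amplitude * amp_scale[1]])
        low = i in low_ids
        qlo, qhi = cfg.low_quality_range if low else cfg.quality_range
        quality = float(rng.uniform(qlo, qhi))
        gains = {c: cfg.erd_depth(c) * quality for c in CONDITIONS}
        phases = cfg.evoked_phase_jitter * rng.standard_normal(4)
        latency = cfg.evoked_latency * float(
            rng.lognormal(0.0, cfg.evoked_latency_jitter))
        profiles.append(SubjectProfile(
            subject_id=i + 1, mixing_matrix=mixing, source_band_powers=powers,
            erd_gains=gains, performer_quality=quality, low_quality=low,
            evoked_phases=phases, evoked_latency=latency))
    return profiles


def _narrowband_noise(rng, n_epochs, n_samples, sfreq, center) -> np.ndarray:
    """Gaussian noise band-limited to center +/- 1.5 Hz, unit variance per epoch."""
    lo, hi = center - _SOURCE_HALF_BW, center + _SOURCE_HALF_BW
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    x = rng.standard_normal((n_epochs, n_samples))
    x = signal.sosfiltfilt(sos, x, axis=-1)
    x /= np.maximum(x.std(axis=-1, keepdims=True), 1e-12)
    return x


def _pink_noise(rng, shape, sfreq, exponent) -> np.ndarray:
    """1/f^exponent background via spectral shaping, unit variance."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = rng.standard_normal(shape[:-1] + (len(freqs),)) + \
        1j * rng.standard_normal(shape[:-1] + (len(freqs),))
    x = np.fft.irfft(spec * scale, n=n, axis=-1)
    x /= np.maximum(x.std(axis=-1, keepdims=True), 1e-12)
    return x


def _evoked_burst(times, f0, phase, latency, width) -> np.ndarray:
    """Cue-locked narrow-band burst: Gaussian envelope around `latency`,
    carrier at the source frequency, zero before the cue."""
    env = np.exp(-0.5 * ((times - latency) / width) ** 2)
    return env * np.cos(2 * np.pi * f0 * (times - latency) + phase) * (times >= 0)


def _erd_gain(times, depth) -> np.ndarray:
    """Amplitude gain over time: 1 before the cue, sqrt(1 - depth) after it,
    with a raised-cosine ramp so the band-power suppression factor is
    (1 - depth) in the post-cue window."""
    ramp = np.clip(times / _ERD_RAMP, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * ramp)
    return np.sqrt(1.0 - depth * ramp)


def simulate_subject(profile: SubjectProfile, cfg: SimConfig, condition: str) -> EpochSet:
    """Simulate one subject/condition block of epochs.

    Left-hand epochs (label +1) suppress the right-hemisphere (contralateral)
    mu/beta sources by the condition's ERD depth; the ipsilateral sources are
    suppressed by depth * (1 - lateralization).  The rest condition has no
    suppression."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = _rng(cfg, 1, profile.subject_id, _COND_CODE[condition])
    n_ep, n_ch, n_s = cfg.n_epochs_per_condition, cfg.n_channels, cfg.n_samples
    times = cfg.epoch_window[0] + np.arange(n_s) / cfg.sfreq

    n_plus = int(round(n_ep * cfg.class_balance))
    labels = np.concatenate([np.ones(n_plus, int), -np.ones(n_ep - n_plus, int)])
    labels = labels[rng.permutation(n_ep)]

    depth = profile.erd_gains[condition]
    lat = cfg.lateralization(condition)
    d_contra, d_ipsi = depth, depth * (1.0 - lat)

    centers = (cfg.mu_freq, cfg.mu_freq, cfg.beta_freq, cfg.beta_freq)
    hemis = ("L", "R", "L", "R")  # hemisphere of each source
    phases = (profile.evoked_phases if profile.evoked_phases is not None
              else np.zeros(4))
    sources = np.empty((4, n_ep, n_s))
    for k, (f0, hemi) in enumerate(zip(centers, hemis)):
        s = _narrowband_noise(rng, n_ep, n_s, cfg.sfreq, f0)
        if condition != "rest":
            # phase-locked component, identical across epochs, subject to
            # the same ERD gain as the induced rhythm
            s = s + cfg.evoked_amplitude * _evoked_burst(
                times, f0, phases[k], profile.evoked_latency, cfg.evoked_width)
            # label +1 = left hand -> contralateral hemisphere is R
            d_for_label = {+1: d_contra if hemi == "R" else d_ipsi,
                           -1: d_contra if hemi == "L" else d_ipsi}
            gain = np.stack([_erd_gain(times, d_for_label[int(y)]) for y in labels])
            s = s * gain
        sources[k] = s * profile.source_band_powers[k]

    data = np.einsum("ck,kes->ecs", profile.mixing_matrix, sources)
    data += cfg.background_sd * _pink_noise(
        rng, (n_ep, n_ch, n_s), cfg.sfreq, cfg.background_exponent)
    data += cfg.sensor_noise_sd * rng.standard_normal((n_ep, n_ch, n_s))

    return EpochSet(data=data, labels=labels, condition=condition,
                    modality=cfg.modality, subject_id=profile.subject_id,
                    sfreq=cfg.sfreq, t0=cfg.epoch_window[0])


def simulate_pool(cfg: SimConfig, conditions=CONDITIONS) -> dict[int, dict[str, EpochSet]]:
    """Simulate every subject under every requested condition.

    Returns {subject_id: {condition: EpochSet}}.  Per-subject/condition random
    streams are derived from the master seed, so pools are reproducible and
    conditions are independent draws."""
    profiles = make_profiles(cfg)
    return {p.subject_id: {c: simulate_subject(p, cfg, c) for c in conditions}
            for p in profiles}
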
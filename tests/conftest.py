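"""Shared scaled-down study configurations and cached simulated pools.

Tests run at a reduced problem size (6 subjects, 16 channels, 250 Hz,
40 epochs of 2 s) that preserves the structure of the full study while
keeping the suite fast; a few tests use the full-scale defaults where the
shape itself is the point.
"""

import numpy as np
import pytest

from mitransfer.preprocessing import PreprocConfig, preprocess
from mitransfer.synthetic import SimConfig, make_profiles, simulate_pool

SMALL = dict(n_subjects=6, n_channels=16, sfreq=250.0,
             epoch_window=(-0.5, 1.5), n_epochs_per_condition=40,
             n_low_quality=2)

SMALL_PP = PreprocConfig(epoch_window=(-0.5, 1.5), baseline_window=(-0.5, 0.0),
                         decimation_factor=2)


def small_config(seed=7, **overrides) -> SimConfig:
    kw = dict(SMALL)
    kw.update(overrides)
    return SimConfig(seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def small_profiles(small_cfg):
    return make_profiles(small_cfg)


@pytest.fixture(scope="session")
def small_pool(small_cfg):
    """Preprocessed small-scale pool (band-passed, baseline-corrected)."""
    pool = simulate_pool(small_cfg)
    return {sid: {c: preprocess(e, SMALL_PP) for c, e in conds.items()}
            for sid, conds in pool.items()}


@pytest.fixture(scope="session")
def ideal_subject():
    """One high-SNR, fully lateralized subject (MI + rest), preprocessed."""
    cfg = small_config(seed=11, erd_depth_mi=0.8, lateralization_mi=1.0,
                       sensor_noise_sd=0.3, background_sd=0.5,
                       n_low_quality=0, quality_range=(1.0, 1.0))
    prof = make_profiles(cfg)[0]
    from mitransfer.synthetic import simulate_subject
    mi = preprocess(simulate_subject(prof, cfg, "MI"), SMALL_PP)
    rest = preprocess(simulate_subject(prof, cfg, "rest"), SMALL_PP)
    return {"cfg": cfg, "profile": prof, "MI": mi, "rest": rest}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
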
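"""Shared fixtures: small synthetic sessions and analysis-scale configs."""

from __future__ import annotations

import pytest

from photosleep.photometry import preprocess
from photosleep.simulate import SimConfig, simulate_session
from photosleep.studies import coupling_config

__all__ = ["coupling_config"]


@pytest.fixture(scope="session")
def small_session():
    """One hour, low sampling rates; EEG/EMG + photometry with defaults."""
    cfg = SimConfig(duration=3600.0, seed=7, eeg_fs=256.0, photo_fs=10.0)
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def coupling_session():
    """Lag-23 dual-channel session plus its preprocessed z-scored traces."""
    cfg = coupling_config(seed=11)
    s = simulate_session(cfg, with_eeg=False)
    ta = preprocess(s.photo["a"], background=cfg.background)
    tb = preprocess(s.photo["b"], background=cfg.background)
    return s, ta, tb
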
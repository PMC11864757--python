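"""Shared fixtures: small synthetic sessions with detected events.

Session-scoped fixtures keep generation cost paid once per run; tests that
need custom study conditions build their own configs locally.
"""

from __future__ import annotations

import numpy as np
import pytest

from epnpop import GeneratorConfig, generate_session
from epnpop.kinematics_events import compute_kinematics, detect_events
from epnpop.session_io import AnalysisConfig


@pytest.fixture(scope="session")
def small_session():
    """Noiseless 220-trial, 6-unit session with full condition coverage."""
    cfg = GeneratorConfig(n_trials=220, n_units=6, seed=11)
    bundle, gt = generate_session(cfg)
    return cfg, bundle, gt


@pytest.fixture(scope="session")
def small_session_events(small_session):
    cfg, bundle, _ = small_session
    kin = compute_kinematics(bundle.tracking, bundle.trials, arena_side=cfg.arena_side)
    events, flagged = detect_events(kin, bundle.trials, bundle.licks, AnalysisConfig())
    return kin, events, flagged


@pytest.fixture(scope="session")
def tiny_session():
    """Very small session for structural tests (fast to regenerate)."""
    cfg = GeneratorConfig(n_trials=25, n_units=3, seed=5)
    bundle, gt = generate_session(cfg)
    return cfg, bundle, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
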
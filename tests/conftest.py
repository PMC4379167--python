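"""Shared fixtures: small synthetic systems reused across test modules."""

import numpy as np
import pytest

from dimerkin.interfaces import detect_dimer_events
from dimerkin.synthetic import (
    AssociationRule,
    CTRWField,
    WaitingTime,
    simulate_ctrw_tracers,
    simulate_protomer_bd,
)

TWO_RULES = (
    AssociationRule(("TM1", "TM2"), ("TM4", "TM5"), p_bind=1.0),
    AssociationRule(("TM5",), ("TM5",), p_bind=1.0),
)


@pytest.fixture(scope="session")
def bd_run():
    """One 16-protomer Brownian run with two association rules."""
    traj, truth = simulate_protomer_bd(
        16, 600.0, 1.0, 0.01, TWO_RULES, duration=4000.0, dt=2.0, seed=11, save_stride=5
    )
    return traj, truth


@pytest.fixture(scope="session")
def bd_detection(bd_run):
    traj, _ = bd_run
    events, maps = detect_dimer_events(traj, cutoff=8.0, min_residues=6, min_persist_frames=3)
    return events, maps


@pytest.fixture(scope="session")
def ctrw_exponential():
    """Homogeneous exponential CTRW ensemble (finely sampled)."""
    field = CTRWField(d=10.0, bulk=WaitingTime("exponential", 10.0))
    return simulate_ctrw_tracers(field, 60, 4000.0, seed=1, dt=10.0 / 80.0)


@pytest.fixture(scope="session")
def ctrw_pareto():
    """Heavy-tailed (Pareto, α=2.2) CTRW ensemble."""
    field = CTRWField(d=10.0, bulk=WaitingTime("pareto", 10.0, shape=2.2))
    return simulate_ctrw_tracers(field, 40, 3000.0, seed=2, dt=10.0 / 80.0)
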
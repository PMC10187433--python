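"""Shared fixtures: simulated populations are session-scoped because the
switch ODE integration dominates generation cost and the populations are
read-only inputs for many tests."""

from __future__ import annotations

import numpy as np
import pytest

from redoxtf import DEFAULT_PARAMS, DosePreset, fit_thresholds
from redoxtf.pipeline import substream
from redoxtf.simulate import generate_population, generate_snapshot


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session")
def control_snapshot():
    """Untreated (dose 0) snapshot population used for threshold fitting."""
    return generate_snapshot(2000, DosePreset.for_dose(0.0), seed=11)


@pytest.fixture(scope="session")
def thresholds(control_snapshot):
    return fit_thresholds(control_snapshot, q=0.99)


@pytest.fixture(scope="session")
def pop_by_dose():
    """Trajectory populations (n=200) at the study doses."""
    return {dose: generate_population(
                200, DosePreset.for_dose(dose),
                seed=substream(23, f"traj:{dose:g}"))
            for dose in (50.0, 80.0, 100.0, 300.0)}


@pytest.fixture(scope="session")
def snapshot_by_dose():
    """Snapshot populations (n=1000) across the dose presets."""
    return {dose: generate_snapshot(
                1000, DosePreset.for_dose(dose), seed=substream(11, f"s:{dose:g}"))
            for dose in (20.0, 50.0, 80.0, 100.0, 200.0, 300.0)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
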
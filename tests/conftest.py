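"""Shared fixtures: forward-model defaults and rendered/measured stacks.

The expensive image-based fixtures (27-scan stacks, pipeline runs) are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

import octinflate as oi
from octinflate.pipeline import RunConfig, run_pipeline

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> oi.ForwardModelParams:
    return oi.ForwardModelParams()


@pytest.fixture(scope="session")
def cycle_schedule() -> oi.PressureSchedule:
    return oi.PressureSchedule.default_cycle()


@pytest.fixture(scope="session")
def cycle_states(cycle_schedule, params):
    return oi.simulate_geometry(cycle_schedule, params)


@pytest.fixture(scope="session")
def noiseless_optics() -> oi.OpticsConfig:
    return oi.OpticsConfig(speckle_sigma=0.0, seed=42)


@pytest.fixture(scope="session")
def default_optics() -> oi.OpticsConfig:
    return oi.OpticsConfig(seed=42)


@pytest.fixture(scope="session")
def noiseless_measured(cycle_states, cycle_schedule, noiseless_optics, params):
    """Geometry series measured from a noiseless full-cycle stack."""
    scans = oi.render_stack(cycle_states, noiseless_optics)
    return oi.measure_stack(scans, cycle_schedule, H2_mm=params.H2)


@pytest.fixture(scope="session")
def speckled_measured(cycle_states, cycle_schedule, default_optics, params):
    """Geometry series measured from a default-speckle full-cycle stack."""
    scans = oi.render_stack(cycle_states, default_optics)
    return oi.measure_stack(scans, cycle_schedule, H2_mm=params.H2)


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two end-to-end runs with identical configuration (for determinism)."""
    root = tmp_path_factory.mktemp("pipeline")
    cfg_a = RunConfig(out_dir=str(root / "a"), seed=7)
    cfg_b = RunConfig(out_dir=str(root / "b"), seed=7)
    return run_pipeline(cfg_a), run_pipeline(cfg_b)
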
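"""Shared fixtures: canonical parameter sets and reduced-scale grids.

Unit and property tests run on a coarsened thermal grid (100 µm lateral,
350 µm axial over ±2 × ±5 mm) so the whole suite stays fast; the
acceptance tests use the full-resolution conditions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import usfsim as u

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> u.RunConfig:
    """Canonical full-resolution configuration."""
    return u.RunConfig()


@pytest.fixture(scope="session")
def small_config() -> u.RunConfig:
    """Reduced-scale configuration for fast dynamic tests."""
    cfg = u.RunConfig()
    cfg.grids.dx = cfg.grids.dy = 100e-6
    cfg.grids.dz = 350e-6
    cfg.grids.Lx = cfg.grids.Ly = 2e-3
    cfg.grids.Lz = 5e-3
    return cfg


@pytest.fixture(scope="session")
def small_source(small_config) -> u.HeatSource:
    return small_config.heat_source()


@pytest.fixture(scope="session")
def tissue() -> u.TissueThermal:
    return u.TissueThermal()


@pytest.fixture(scope="session")
def agent() -> u.NanoagentSpec:
    return u.NanoagentSpec.from_midpoint(
        Q0=0.05, R0=2.6, T_M=38.7, sigma=1.0 / (3.0 * np.sqrt(2.0))
    )


@pytest.fixture(scope="session")
def optics_ex() -> u.OpticalMedium:
    return u.derive_optics(15.0, 1500.0, epsilon=6.09e6)


@pytest.fixture(scope="session")
def optics_fl() -> u.OpticalMedium:
    return u.derive_optics(12.0, 1700.0, epsilon=6.54e5)


@pytest.fixture(scope="session")
def geometry(optics_ex) -> u.BoundaryGeometry:
    return u.BoundaryGeometry.for_placement("top", 10e-3, optics_ex)


@pytest.fixture(scope="session")
def sd() -> u.SourceDetectorConfig:
    return u.SourceDetectorConfig()


@pytest.fixture(scope="session")
def small_thermal(small_source, tissue) -> u.ThermalField:
    """Stored 10 ms-cadence snapshots on the reduced grid (1 s span)."""
    times = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 9)
    return u.solve_bioheat(small_source, tissue, snapshot_times=times)
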
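"""Shared fixtures: solvent conditions, chip, and session-scoped basis libraries."""

import numpy as np
import pytest

from smds import chip, physics
from smds.chip import ChipGeometry, FlowSettings, SolverOptions, simulate_basis

#: Reduced solver settings used throughout the suite: coarse enough to keep a
#: basis simulation around a second, fine enough for percent-level fits.
FAST_OPTS = SolverOptions(n_transverse=101, n_depth=9, max_steps=120)


@pytest.fixture(scope="session")
def cond():
    return physics.SolventConditions()


@pytest.fixture(scope="session")
def geom():
    return ChipGeometry()


@pytest.fixture(scope="session")
def flow100():
    return FlowSettings(100.0)


@pytest.fixture(scope="session")
def basis_small(geom, flow100, cond):
    """45 log-spaced radii over 0.5-300 nm; the workhorse fitting basis."""
    return simulate_basis(geom, flow100, cond, np.geomspace(0.5, 300.0, 45), FAST_OPTS)


@pytest.fixture(scope="session")
def basis_tiny(geom, flow100, cond):
    """Five-decade sanity grid {1, 3, 10, 30, 100} nm."""
    return simulate_basis(geom, flow100, cond,
                          np.array([1.0, 3.0, 10.0, 30.0, 100.0]), FAST_OPTS)


def make_step_profile_from_basis(basis, r_h_nm, gap_um=50.0):
    """Noiseless step-style profile sampled exactly on the basis grid."""
    from smds.profiles import DiffusionProfile

    W = basis.width_um
    bounds = [(k * (W + gap_um), k * (W + gap_um) + W)
              for k in range(basis.n_crossings)]
    coords = np.concatenate([lo + basis.transverse_um for lo, _ in bounds])
    vals = np.concatenate(list(basis.interpolate(r_h_nm)))
    return DiffusionProfile(coords, vals, "continuous", bounds)
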
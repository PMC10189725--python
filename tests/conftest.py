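"""Shared fixtures: reference geometries and cached simulation runs.

The expensive PDE runs are session-scoped so each is computed once and
shared by the unit and acceptance tests that compare against it.
"""

import numpy as np
import pytest
from hypothesis import settings

from cuticle_uptake import (
    Geometry,
    GridSpec,
    simulate_1d,
    simulate_radial_exterior,
    simulate_uptake,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: reference assay geometry: 450 um deposit radius, 50 nm maize cuticle,
#: 20-droplet array
PAPER_GEOMETRY = Geometry(r_dep_m=450e-6, z_max_m=50e-9, n_droplets=20)

#: transport parameters inferred for the lipophilic fungicide on maize
PAPER_D_CUT = 1.24e-18  # m^2 s^-1
PAPER_C_SAT_CUT = 1.87e6  # ppm = g m^-3


@pytest.fixture(scope="session")
def geom_paper() -> Geometry:
    return PAPER_GEOMETRY


@pytest.fixture(scope="session")
def master_paper(geom_paper):
    """Master dimensionless curve at the assay's Z_max, spanning the data range."""
    spec = GridSpec(T_min=1e-10, T_max=1e-4, steps_per_decade=40)
    return simulate_uptake(geom_paper.Z_max, spec)


@pytest.fixture(scope="session")
def sim_z10():
    """Thick-cuticle run (Z_max = 10): semi-infinite disk regime."""
    spec = GridSpec(T_min=1e-4, T_max=1e2, steps_per_decade=40)
    return simulate_uptake(10.0, spec)


@pytest.fixture(scope="session")
def sim_thin():
    """Thin-cuticle run (Z_max = 0.01): full transition to the rim-cylinder regime."""
    spec = GridSpec(T_min=1e-6, T_max=10.0, steps_per_decade=40)
    return simulate_uptake(0.01, spec)


@pytest.fixture(scope="session")
def sim_z1e3_transition():
    """Very thin cuticle (Z_max = 1e-3) run spanning its saturation transition."""
    Z = 1e-3
    spec = GridSpec(T_min=1e-2 * Z**2, T_max=100 * Z**2, steps_per_decade=40)
    return simulate_uptake(Z, spec)


@pytest.fixture(scope="session")
def curve_1d_unit():
    """1D plane-sheet run at Z_max = 1 over the full saturation decay."""
    spec = GridSpec(T_min=1e-2, T_max=10.0, steps_per_decade=80)
    return simulate_1d(1.0, spec)


@pytest.fixture(scope="session")
def radial_oracle():
    """Exterior-of-cylinder flux density, the oracle for the cylinder limit."""
    return simulate_radial_exterior(1e-3, 1e3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
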
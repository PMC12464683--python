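"""Shared fixtures: a planted ADR problem sampled on a voxel grid, its exact
oracle surrogate, and derived libraries.  Session-scoped because everything
downstream is deterministic and read-only."""

import numpy as np
import pytest

import cedi


@pytest.fixture(scope="session")
def adr_spec():
    # the planted study problem: growth 0.3 /y, vertical advection 0.5 m/y,
    # isotropic diffusion 0.01 m^2/y
    return cedi.ADRSpec()


@pytest.fixture(scope="session")
def adr_field(adr_spec):
    return cedi.analytic_adr_field(adr_spec)


@pytest.fixture(scope="session")
def adr_data(adr_spec, adr_field):
    """Noiseless voxel-grid sample on an isotropically scaled (cubic) box."""
    box, span = cedi.adr_domain(adr_spec, cubic=True)
    return cedi.sample_measurements(
        adr_field, cedi.SamplingSpec(dx=1.5, dt=2.0), (box, span)
    )


@pytest.fixture(scope="session")
def adr_scaling(adr_data):
    return cedi.compute_scaling(adr_data)


@pytest.fixture(scope="session")
def adr_scaled(adr_data, adr_scaling):
    return cedi.apply_scaling(adr_data, adr_scaling)


@pytest.fixture(scope="session")
def adr_oracle(adr_field, adr_scaling):
    return cedi.as_scaled_oracle(adr_field, adr_scaling)


@pytest.fixture(scope="session")
def lib_I(adr_oracle, adr_scaled):
    cat = cedi.standard_catalogue("I")
    table = cedi.build_derivative_table(adr_oracle, adr_scaled.points(), cat.needed_keys())
    return cedi.build_library(table, cat)


@pytest.fixture(scope="session")
def lib_II(adr_oracle, adr_scaled):
    cat = cedi.standard_catalogue("II")
    table = cedi.build_derivative_table(adr_oracle, adr_scaled.points(), cat.needed_keys())
    return cedi.build_library(table, cat)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
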
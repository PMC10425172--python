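"""Shared fixtures: chamber geometry, plume fields, gradient contexts.

Heavier fixtures are session-scoped so the marching solver and gradient
interpolators are built once.
"""

import numpy as np
import pytest

from odorscape.navigation_analysis import GradientContext
from odorscape.plume_model import ChamberGeometry, PlumeParams, steady_plume_field


@pytest.fixture(scope="session")
def geom() -> ChamberGeometry:
    return ChamberGeometry()


@pytest.fixture(scope="session")
def plume_params() -> PlumeParams:
    return PlumeParams(source_concentration_Co=100.0, flow_speed_v=0.5, diffusivity_D=0.08)


@pytest.fixture(scope="session")
def cone_field(plume_params, geom):
    return steady_plume_field(plume_params, geom)


@pytest.fixture(scope="session")
def cone_context(cone_field) -> GradientContext:
    return GradientContext.from_field(cone_field)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
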
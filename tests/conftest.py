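"""Shared fixtures.

The expensive objects (curvature fields, the staged wave segment) are
session-scoped: staging a segment takes ~20 s and several experiment tests
reuse it, as do the acceptance checks.
"""

import numpy as np
import pytest

import sdsim as sd
from sdsim.curvature import robust_curvature_field
from sdsim.experiments import ScatterConfig, stage_segment


@pytest.fixture(scope="session")
def sphere10():
    """Icosphere R = 10 at the default test refinement (642 vertices)."""
    return sd.make_sphere(10.0, 3)


@pytest.fixture(scope="session")
def sphere10_fine():
    return sd.make_sphere(10.0, 4)


@pytest.fixture(scope="session")
def torus31():
    return sd.make_torus(3.0, 1.0, 72, 28)


@pytest.fixture(scope="session")
def sphere10_field(sphere10):
    return robust_curvature_field(sphere10)


@pytest.fixture(scope="session")
def torus31_field(torus31):
    return robust_curvature_field(torus31)


@pytest.fixture(scope="session")
def bump_params():
    """Published bump-study parameter set."""
    return sd.RDParameters.preset("bump-study")


@pytest.fixture(scope="session")
def scatter_config():
    """Desk-scale scattering geometry: tall enough for tip-grazing offsets."""
    return ScatterConfig(extent=(120.0, 100.0))


@pytest.fixture(scope="session")
def staged_segment(bump_params, scatter_config):
    """A stabilised wave segment on the flat periodic staging sheet."""
    segment, staging = stage_segment(bump_params, scatter_config)
    return segment, staging
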
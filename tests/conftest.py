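"""Shared fixtures: small phantoms and meshes, built once per session."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from paleofract.materials import default_cancellous_card
from paleofract.phantoms import (
    ParaboloidPatchSpec,
    PhantomSpec,
    generate_phantom,
    generate_tet_phantom,
)


@pytest.fixture(scope="session")
def fractured_spec():
    return PhantomSpec(
        fracture_plane=ParaboloidPatchSpec(), taphonomic_cracks=2, seed=1
    )


@pytest.fixture(scope="session")
def fractured_phantom(fractured_spec):
    return generate_phantom(fractured_spec)


@pytest.fixture(scope="session")
def phantom_mesh():
    """~12k-element capped-cylinder mesh with a planted fracture surface."""
    spec = PhantomSpec(fracture_plane=ParaboloidPatchSpec(), seed=0)
    mesh, density = generate_tet_phantom(spec, 12000)
    return spec, mesh, density


@pytest.fixture(scope="session")
def het_card():
    return default_cancellous_card(PhantomSpec().cancellous_class_densities)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
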
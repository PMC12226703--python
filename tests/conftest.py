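"""Shared fixtures: analytic meshes and small, fast phantom environments."""

import numpy as np
import pytest

from ablaplan.environment import build_environment
from ablaplan.mesh import IndexedMesh
from ablaplan.objectives import PlannerParams
from ablaplan.phantoms import PhantomConfig, make_phantom
from ablaplan.primitives import ellipsoid, icosphere


@pytest.fixture(scope="session")
def sphere10():
    """Radius-10 icosphere, the reference ablation-zone geometry."""
    return icosphere(10.0, 3)


@pytest.fixture(scope="session")
def sphere10_indexed(sphere10):
    return IndexedMesh(sphere10)


@pytest.fixture(scope="session")
def concentric_env():
    """Spheres-only environment: skin R=80, liver R=40, tumor r=5, margin 5.

    Tumor at the origin, no critical structures; analytic geometry makes
    chord lengths and entry angles exactly computable.
    """
    skin = icosphere(80.0, 3)
    liver = icosphere(40.0, 3)
    tumor = icosphere(5.0, 3)
    return build_environment(skin, liver, tumor, margin=5.0, spacing=2.0)


@pytest.fixture(scope="session")
def elongated_env():
    """Environment whose skin allows >150 mm trajectories (length-cap tests)."""
    skin = ellipsoid((170.0, 80.0, 80.0), subdivisions=3)
    liver = icosphere(40.0, 3)
    tumor = icosphere(5.0, 3)
    return build_environment(skin, liver, tumor, margin=5.0, spacing=2.0)


@pytest.fixture(scope="session")
def subcapsular_env():
    """Tumor close to the liver capsule: steep-angle filters become active."""
    skin = icosphere(80.0, 3)
    liver = icosphere(40.0, 3)
    tumor = icosphere(2.0, 2, center=(0.0, 0.0, 38.0))
    return build_environment(skin, liver, tumor, margin=2.0, spacing=1.0)


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small single-needle-solvable phantom used by the operator tests."""
    return make_phantom(
        PhantomConfig(tumor_diameter=8.0, margin_mm=3.0, spacing_mm=2.0, seed=11)
    )


@pytest.fixture(scope="session")
def small_phantom():
    """The canonical 10 mm sphere tumor with 5 mm margin."""
    return make_phantom(
        PhantomConfig(tumor_diameter=10.0, margin_mm=5.0, spacing_mm=2.0, seed=1)
    )


@pytest.fixture()
def params():
    return PlannerParams(pop_size=8, n_generations=10, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
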
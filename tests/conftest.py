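import numpy as np
import pytest

from photonmc.geometry import Region, Scene, make_cube_phantom, make_sphere_mesh
from photonmc.optics import OpticalProperties
from photonmc.transport import RecorderSpec, RunControls, SourceSpec, run_simulation

#: Homogeneous polyethylene-like phantom properties at 620 nm.
PHANTOM_PROPS = OpticalProperties(mu_a=0.0002, mu_s=11.7, g=0.95, n=1.37)


@pytest.fixture(scope="session")
def cube_mesh():
    return make_cube_phantom(10.0, 1)


@pytest.fixture(scope="session")
def cube_scene(cube_mesh):
    """10 mm homogeneous cube phantom in air."""
    return Scene([Region("cube", cube_mesh, PHANTOM_PROPS)], ambient_n=1.0)


@pytest.fixture(scope="session")
def nested_scene(cube_mesh):
    """Cube phantom with a centered unit-sphere inclusion."""
    inner = make_sphere_mesh(1.0, refinement=2)
    return Scene(
        [
            Region("cube", cube_mesh, PHANTOM_PROPS),
            Region("core", inner, OpticalProperties(0.1, 5.0, 0.9, 1.37), parent="cube"),
        ]
    )


@pytest.fixture(scope="session")
def offset_source_result(cube_scene):
    """BLT-style run: isotropic source 3 mm below the +z face, roulette off,
    1e5 photons, 300x300 face grids.  Shared by conservation / recording tests."""
    source = SourceSpec(kind="internal", volume=("sphere", (0.0, 0.0, 2.0), 0.5))
    controls = RunControls(n_photons=100_000, seed=11, roulette_threshold=0.0)
    return run_simulation(
        cube_scene, source, controls, recorders=RecorderSpec(face_grid=(300, 300))
    )


@pytest.fixture(scope="session")
def centered_source_result(cube_scene):
    """Centered isotropic source, 1e5 photons — the symmetry workhorse."""
    source = SourceSpec(kind="internal", volume=("sphere", (0.0, 0.0, 0.0), 0.5))
    controls = RunControls(n_photons=100_000, seed=5, roulette_threshold=0.0)
    return run_simulation(
        cube_scene, source, controls, recorders=RecorderSpec(face_grid=(300, 300))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
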
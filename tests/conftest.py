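import numpy as np
import pytest
import trimesh

import abcline as ab


@pytest.fixture(scope="session")
def default_skull() -> ab.AnatomyModel:
    """Default ellipsoidal skull phantom at full mesh resolution."""
    return ab.generate_skull()


@pytest.fixture(scope="session")
def small_skull() -> ab.AnatomyModel:
    """Coarser skull for the more expensive voxel-grid tests."""
    return ab.generate_skull(ab.SkullParams(subdivisions=3))


@pytest.fixture(scope="session")
def sphere_mesh() -> trimesh.Trimesh:
    """Unit-test sphere of radius 100 mm centred at the origin."""
    mesh = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices) * 100.0,
        faces=np.asarray(mesh.faces),
        process=False,
    )


@pytest.fixture(scope="session")
def origin_ellipsoid_mesh() -> trimesh.Trimesh:
    """Ellipsoid with skull semi-axes but centred at the origin."""
    mesh = trimesh.creation.icosphere(subdivisions=5, radius=1.0)
    return trimesh.Trimesh(
        vertices=np.asarray(mesh.vertices) * np.array([70.0, 90.0, 65.0]),
        faces=np.asarray(mesh.faces),
        process=False,
    )


@pytest.fixture(scope="session")
def cohort_80(default_skull) -> "pd.DataFrame":  # noqa: F821
    """End-to-end measured cohort of 80 subject-sides (seed 7)."""
    from abcline.config import RunConfig
    from abcline.pipeline import build_cohort_table

    return build_cohort_table(RunConfig(seed=7))
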
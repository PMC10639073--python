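import numpy as np
import pytest

import polsensor as ps


@pytest.fixture
def default_site():
    """Deoxy active site at the locked-mode geometry."""
    return ps.make_active_site(ps.SiteParams())


@pytest.fixture
def ribo_site():
    return ps.make_active_site(ps.SiteParams(sugar="ribo", sensor_angle=120.0,
                                             gate_distance=4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20230828)


def random_rigid_transform(rng) -> ps.RigidTransform:
    """Uniform random proper rotation + bounded translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return ps.RigidTransform(R, t)


def rigidly_move(structure: ps.Structure, transform: ps.RigidTransform) -> ps.Structure:
    return structure.with_coords(ps.apply_transform(transform, structure.coords))
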
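import numpy as np
import pytest

from helixkink.core import MembraneFrame
from helixkink.synthetic import KinkSpec, build_ideal_helix, build_kinked_helix


@pytest.fixture(scope="session")
def ideal_helix():
    """Straight ideal alpha-helix over APP 686-728 numbering."""
    return build_ideal_helix()


@pytest.fixture(scope="session")
def kinked_helix_30():
    """Helix kinked 30 deg at the Gly709 hinge."""
    return build_kinked_helix(kink=KinkSpec(target_bend_deg=30.0))


@pytest.fixture(scope="session")
def membrane_frame():
    return MembraneFrame()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def centered_tm_helix(ideal_helix):
    """Straight helix rigidly placed with its TM axis along z, centered at z=0."""
    from helixkink.geometry import fit_helix_axis

    ax = fit_helix_axis(ideal_helix, (700, 723))
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ax.direction, z)
    s = np.linalg.norm(v)
    c = float(np.dot(ax.direction, z))
    if s < 1e-12:
        R = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    t = -R @ ax.centroid
    return ideal_helix.transformed(R, t)


def random_rotation(rng) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
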
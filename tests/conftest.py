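import numpy as np
import pytest

from wolfreg.geometry import AffineParams, compose_matrix, invert_matrix, apply_transform
from wolfreg.shapes import make_cylinder, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cylinder_pair():
    """The fixed-transform cylinder benchmark pair (source, target, truth)."""
    cloud = make_cylinder(n_points=500, seed=0)
    return make_pair(cloud)


@pytest.fixture(scope="session")
def known_params_pair():
    """A pair whose exact generative parameters are known in advance.

    The target is a cylinder cloud; the source is the target pushed through
    the inverse of compose(params), so registering source onto target has
    the exact solution ``params`` with MSE 0.
    """
    params = AffineParams(
        tx=0.3, ty=-0.2, tz=0.1,
        phi_x=10.0, phi_y=-5.0, phi_z=15.0,
        sx=1.05, sy=0.95, sz=1.1,
        sh1=0.05, sh2=-0.03, sh3=0.02, sh4=0.04, sh5=-0.05, sh6=0.01,
    )
    target = make_cylinder(n_points=300, seed=7)
    H = compose_matrix(params)
    source = apply_transform(target, invert_matrix(H))
    return params, source, target
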
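import numpy as np
import pytest

from spheremark import Camera, Intrinsics, Pose, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_camera():
    """Identity pose, fx=fy=1000, principal point (500, 500), no distortion."""
    return Camera(
        id="cam",
        image_ref="cam.jpg",
        intrinsics=Intrinsics(fx=1000, fy=1000, cx=500, cy=500, width=1000, height=1000),
        pose=Pose(R=np.eye(3), t=np.zeros(3)),
    )


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free 30-camera synthetic sphere with 10 specimen points + token."""
    return generate_scene(SceneSpec(n_cameras=30, n_points=10, rng_seed=1))


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q
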
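import numpy as np
import pytest

from dentopo import TriangleMesh
from dentopo.synthetic import SyntheticToothSpec, make_synthetic_tooth


@pytest.fixture(scope="session")
def unit_cube() -> TriangleMesh:
    """Closed unit cube: 8 vertices, 12 triangles, area 6, outward winding."""
    import trimesh
    b = trimesh.creation.box(extents=(1, 1, 1))
    return TriangleMesh(np.asarray(b.vertices), np.asarray(b.faces))


@pytest.fixture(scope="session")
def small_tooth():
    """Coarse synthetic crown pair + landmarks + truth (fast, reused)."""
    spec = SyntheticToothSpec(target_faces=4000, seed=11)
    return make_synthetic_tooth(spec)


@pytest.fixture(scope="session")
def medium_tooth():
    """Default-like crown at moderate resolution."""
    spec = SyntheticToothSpec(target_faces=12000, seed=5)
    return make_synthetic_tooth(spec)


def random_rigid(seed: int):
    """A random proper rigid transform (rotation matrix + translation)."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(3, 3))
    q, _ = np.linalg.qr(a)
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.normal(scale=5.0, size=3)
    return q, t
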
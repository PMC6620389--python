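import numpy as np
import pytest

from wormneurite import NeuronTree, SwcNode


def chain_tree(points, radii=None, codes=None):
    """A simple path tree through the given 3D points."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    radii = np.full(n, 0.5) if radii is None else np.asarray(radii, float)
    codes = np.full(n, 3, int) if codes is None else np.asarray(codes, int)
    nodes = [
        SwcNode(
            id=i + 1,
            structure_code=int(codes[i]),
            x=points[i, 0],
            y=points[i, 1],
            z=points[i, 2],
            radius=float(radii[i]),
            parent_id=i if i > 0 else -1,
        )
        for i in range(n)
    ]
    return NeuronTree(nodes)


def corner_polyline(angle_deg, arm_length=5.0, spacing=0.2, rotation=None):
    """Two straight arms meeting at the origin with a given interior angle.

    Points run from the tip of the first arm, through the apex, to the tip
    of the second arm.  ``rotation`` optionally applies a 3x3 matrix.
    """
    th = np.radians(180.0 - angle_deg)
    u = np.array([1.0, 0.0, 0.0])
    v = np.array([np.cos(th), np.sin(th), 0.0])
    n_arm = int(arm_length / spacing)
    pts = (
        [-u * spacing * k for k in range(n_arm, 0, -1)]
        + [np.zeros(3)]
        + [v * spacing * k for k in range(1, n_arm + 1)]
    )
    pts = np.array(pts)
    if rotation is not None:
        pts = pts @ np.asarray(rotation).T
    return pts


def random_rotation(rng):
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
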
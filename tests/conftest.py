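import numpy as np
import pytest

from plateforge import synthetic
from plateforge.meshcore import SurfaceMesh


@pytest.fixture(scope="session")
def unit_cube():
    return synthetic.box((1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def icosphere10():
    return synthetic.icosphere(10.0, 3)


@pytest.fixture(scope="session")
def flat100():
    return synthetic.flat_grid(100.0, 100.0, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent oracles (deliberately different formulations from the package)
# ---------------------------------------------------------------------------

def oracle_point_triangle_distance(p, a, b, c):
    """Closest distance point-to-triangle via plane projection + barycentric
    test + explicit edge-segment distances (not the Ericson construction)."""
    p, a, b, c = (np.asarray(v, dtype=float) for v in (p, a, b, c))
    n = np.cross(b - a, c - a)
    nn = np.dot(n, n)
    best = np.inf
    if nn > 0:
        # project onto the plane and test barycentric containment
        q = p - np.dot(p - a, n) / nn * n
        v0, v1, v2 = b - a, c - a, q - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        denom = d00 * d11 - d01 * d01
        if denom != 0:
            v = (d11 * d20 - d01 * d21) / denom
            w = (d00 * d21 - d01 * d20) / denom
            if v >= 0 and w >= 0 and v + w <= 1:
                best = np.linalg.norm(p - q)
    for s0, s1 in ((a, b), (b, c), (c, a)):
        d = s1 - s0
        t = np.clip(np.dot(p - s0, d) / (d @ d), 0.0, 1.0) if d @ d > 0 else 0.0
        best = min(best, np.linalg.norm(p - (s0 + t * d)))
    return best


def oracle_closest_face(mesh: SurfaceMesh, p):
    """Exhaustive per-triangle minimum; first (lowest) face index on ties."""
    tri = mesh.triangles
    dists = np.array([oracle_point_triangle_distance(p, *t) for t in tri])
    i = int(np.argmin(dists))
    return i, float(dists[i])
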
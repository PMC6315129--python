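import numpy as np
import pytest

from faceasym import SurfaceMesh, make_template


@pytest.fixture(scope="session")
def template30():
    """Mid-resolution symmetric face template shared across tests."""
    return make_template(30)


@pytest.fixture(scope="session")
def plane_mesh():
    """A flat 10x10 grid in the z = 0 plane (100 vertices, known normals)."""
    xs = np.linspace(-1.0, 1.0, 10)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(100)])
    idx = np.arange(100).reshape(10, 10)
    q00, q10 = idx[:-1, :-1].ravel(), idx[1:, :-1].ravel()
    q01, q11 = idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()
    faces = np.concatenate([np.column_stack([q00, q10, q11]),
                            np.column_stack([q00, q11, q01])])
    return SurfaceMesh(verts, faces)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
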
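import numpy as np
import pytest

from debondmetry.mesh_io import TriangleSurface


@pytest.fixture
def unit_square() -> TriangleSurface:
    """Two-triangle unit square in the z = 0 plane, normals toward +z."""
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
    )
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleSurface(vertices, faces)


@pytest.fixture
def random_patch() -> TriangleSurface:
    """Small random-height grid patch (100 vertices) for round-trip tests."""
    rng = np.random.default_rng(42)
    n = 10
    xs, ys = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float))
    z = rng.normal(0, 0.1, (n, n))
    vertices = np.column_stack([xs.ravel(), ys.ravel(), z.ravel()])
    idx = np.arange(n * n).reshape(n, n)
    faces = np.concatenate(
        [
            np.column_stack(
                [idx[:-1, :-1].ravel(), idx[:-1, 1:].ravel(), idx[1:, 1:].ravel()]
            ),
            np.column_stack(
                [idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[1:, :-1].ravel()]
            ),
        ]
    )
    return TriangleSurface(vertices, faces)


def flat_patch(width=4.0, height=4.0, pitch=0.1, z=0.0) -> TriangleSurface:
    """Flat rectangular patch at constant z, outward normal +z."""
    from debondmetry.phantom import PhantomSpec, generate_base_surface

    spec = PhantomSpec(
        patch_extent=(width, height),
        curvature_radii=(np.inf, np.inf),
        mesh_pitch=pitch,
        noise_sd=0.0,
        seed=0,
    )
    surf = generate_base_surface(spec)
    v = surf.vertices.copy()
    v[:, 2] = z  # strip the undulation: exactly planar
    return TriangleSurface(v, surf.faces)
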
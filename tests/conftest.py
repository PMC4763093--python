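import numpy as np
import pytest

from coralmorph.mesh import Mesh

# unit cube: 8 vertices, 12 outward-wound triangles
CUBE_VERTS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom
        [4, 5, 6], [4, 6, 7],  # top
        [0, 1, 5], [0, 5, 4],  # front
        [1, 2, 6], [1, 6, 5],  # right
        [2, 3, 7], [2, 7, 6],  # back
        [3, 0, 4], [3, 4, 7],  # left
    ]
)


@pytest.fixture
def cube() -> Mesh:
    return Mesh(CUBE_VERTS.copy(), CUBE_FACES.copy(), units="cm")


@pytest.fixture
def open_cube() -> Mesh:
    """Cube missing its top face pair: one square boundary loop."""
    return Mesh(CUBE_VERTS.copy(), CUBE_FACES[[0, 1, 4, 5, 6, 7, 8, 9, 10, 11]].copy(), units="cm")


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> Mesh:
    """Icosphere built by trimesh — an implementation-independent fixture."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Mesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64), units="cm")


def uv_hemisphere_shell(radius: float = 1.0, n_theta: int = 32, n_phi: int = 64) -> Mesh:
    """Open hemisphere shell (no base disc): one equatorial boundary loop."""
    from coralmorph.synthetic import _Builder, _hemisphere

    b = _Builder()
    _hemisphere(b, radius, n_theta, n_phi, close_base=False)
    mesh, _ = b.build()
    return mesh


def voxel_volume(mesh: Mesh, h: float) -> float:
    """Brute-force volume by vertical ray casting on an h-spaced column grid.

    For each (x, y) column centre, every triangle crossing the column
    contributes its intersection height; sorted crossings pair into
    inside intervals whose total length, times h², approximates the
    enclosed volume.  Independent of the divergence-theorem path.
    """
    v = mesh.vertices
    f = mesh.faces
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    # offset grid to dodge exact edge/vertex hits
    xs = np.arange(lo[0] + 0.5137 * h, hi[0], h)
    ys = np.arange(lo[1] + 0.4729 * h, hi[1], h)
    crossings: dict = {}
    tri = v[f]  # (m, 3, 3)
    for t in tri:
        txlo, tylo = t[:, 0].min(), t[:, 1].min()
        txhi, tyhi = t[:, 0].max(), t[:, 1].max()
        xi = xs[(xs >= txlo) & (xs <= txhi)]
        yi = ys[(ys >= tylo) & (ys <= tyhi)]
        if len(xi) == 0 or len(yi) == 0:
            continue
        X, Y = np.meshgrid(xi, yi, indexing="ij")
        P = np.stack([X.ravel(), Y.ravel()], axis=1)
        a, b_, c = t[0, :2], t[1, :2], t[2, :2]
        det = (b_[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b_[1] - a[1])
        if det == 0:
            continue  # vertical triangle: measure-zero columns
        w1 = ((P[:, 0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (P[:, 1] - a[1])) / det
        w2 = ((b_[0] - a[0]) * (P[:, 1] - a[1]) - (P[:, 0] - a[0]) * (b_[1] - a[1])) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        z = w0[inside] * t[0, 2] + w1[inside] * t[1, 2] + w2[inside] * t[2, 2]
        for (x, y), zz in zip(P[inside], z):
            crossings.setdefault((round(x, 9), round(y, 9)), []).append(zz)
    total = 0.0
    for zz in crossings.values():
        zz = sorted(zz)
        for k in range(0, len(zz) - 1, 2):
            total += zz[k + 1] - zz[k]
    return total * h * h
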
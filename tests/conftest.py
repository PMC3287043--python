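import numpy as np
import pytest

from lvsolid.splinecore import ControlGrid3D, KnotVector, SolidModel
from lvsolid.geometry import WallPointCloud


def make_identity_cube(degrees=(1, 1, 1), shape=None) -> SolidModel:
    """Solid whose control points sit on their own parameter lattice.

    With linear degrees this is the exact identity map of the unit cube; with
    higher degrees the map is still affine-exact in each control coordinate
    only for linear degrees, so default is trilinear.
    """
    k1, k2, k3 = degrees
    if shape is None:
        shape = (k1 + 1, k2 + 1, k3 + 1)
    nc, nl, nr = shape
    g = np.zeros((nc, nl, nr, 3))
    gi = np.linspace(0, 1, nc)
    gj = np.linspace(0, 1, nl)
    gk = np.linspace(0, 1, nr)
    g[..., 0] = gi[:, None, None]
    g[..., 1] = gj[None, :, None]
    g[..., 2] = gk[None, None, :]
    return SolidModel(ControlGrid3D(g),
                      KnotVector.clamped_uniform(nc, k1),
                      KnotVector.clamped_uniform(nl, k2),
                      KnotVector.clamped_uniform(nr, k3))


def make_random_solid(seed: int, shape=(5, 4, 4), degrees=(3, 3, 3),
                      jitter: float = 0.08) -> SolidModel:
    """Well-shaped random tricubic solid: jittered identity lattice.

    The jitter is small enough relative to the lattice spacing that the
    isoparametric map stays untangled (det J > 0).
    """
    rng = np.random.default_rng(seed)
    base = make_identity_cube((1, 1, 1), shape)
    g = base.grid.points + rng.uniform(-jitter, jitter, base.grid.points.shape)
    k1, k2, k3 = degrees
    return SolidModel(ControlGrid3D(g),
                      KnotVector.clamped_uniform(shape[0], k1),
                      KnotVector.clamped_uniform(shape[1], k2),
                      KnotVector.clamped_uniform(shape[2], k3))


def make_cylinder_cloud(radius: float, height: float = 50.0, n_slices: int = 12,
                        n_phi: int = 32, wall: str = "inner",
                        noise: float = 0.0, seed: int = 0) -> WallPointCloud:
    """Contour rings sampled on a right circular cylinder centred on z."""
    rng = np.random.default_rng(seed)
    z = np.linspace(-height / 2, height / 2, n_slices)
    phi = np.arange(n_phi) * 2 * np.pi / n_phi
    pts = np.empty((n_slices, n_phi, 3))
    pts[..., 0] = radius * np.cos(phi)[None, :]
    pts[..., 1] = radius * np.sin(phi)[None, :]
    pts[..., 2] = z[:, None]
    pts = pts.reshape(-1, 3)
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    sl = np.repeat(np.arange(n_slices), n_phi)
    ring = np.tile(np.arange(n_phi), n_slices)
    return WallPointCloud(pts, sl, ring, wall, 0)


@pytest.fixture
def identity_cube() -> SolidModel:
    return make_identity_cube()


@pytest.fixture
def random_solid() -> SolidModel:
    return make_random_solid(42)
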
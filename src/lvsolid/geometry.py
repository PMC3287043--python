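"""Ventricular geometry: cylindrical coordinates, wall point clouds, surface
fitting, sweeping to a hexahedral control mesh, and trivariate solid fitting.

The modelling pipeline mirrors how slice-stacked short-axis contours are
turned into an analysable solid:

1. segmented endocardial/epicardial contour rings -> :class:`WallPointCloud`
2. per-wall tensor-product surface by linear least squares (:func:`fit_surface`),
   periodic in the circumferential direction
3. inner and outer surfaces swept into a layered hexahedral control mesh
   (:func:`sweep_hex_mesh`)
4. the mesh adopted as the control grid of a trivariate B-spline solid
   (:func:`fit_solid`)

All lengths are millimetres, angles radians.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .splinecore import (
    ControlGrid3D,
    DomainError,
    KnotVector,
    SolidModel,
    SurfaceModel,
    ValidationError,
    basis_matrix,
    make_knot_vector,
)

__all__ = [
    "CylindricalPoint",
    "WallPointCloud",
    "HexControlMesh",
    "SurfaceFit",
    "to_cylindrical",
    "from_cylindrical",
    "solid_to_cylindrical",
    "parameterize_cloud",
    "fit_surface",
    "sweep_hex_mesh",
    "fit_solid",
    "read_cloud_csv",
    "write_cloud_csv",
]

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# Cylindrical coordinates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CylindricalPoint:
    """(r, theta, z) with r >= 0 (mm), theta in [0, 2*pi) (rad), z in mm."""

    r: float
    theta: float
    z: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValidationError("cylindrical radius must be nonnegative")
        if not 0.0 <= self.theta < TWO_PI:
            raise ValidationError("theta must lie in [0, 2*pi)")


def to_cylindrical(point: Sequence[float]) -> CylindricalPoint:
    """Cartesian -> cylindrical with the branch table fixing theta in [0, 2pi).

    Branches: x=0,y>0 -> pi/2; x=0,y<0 -> 3pi/2; x>0,y>=0 -> atan(y/x);
    x<0 -> pi+atan(y/x); x>0,y<0 -> 2pi+atan(y/x).  The axis point x=y=0 maps
    to theta=0 (ventricular walls never contain the long axis; this only
    guards synthetic edge cases).
    """
    x, y, z = (float(v) for v in point)
    if not all(np.isfinite([x, y, z])):
        raise ValidationError("point coordinates must be finite")
    r = float(np.hypot(x, y))
    if x == 0.0:
        if y > 0.0:
            theta = np.pi / 2.0
        elif y < 0.0:
            theta = 3.0 * np.pi / 2.0
        else:
            theta = 0.0
    elif x > 0.0:
        theta = np.arctan(y / x) if y >= 0.0 else TWO_PI + np.arctan(y / x)
    else:  # x < 0
        theta = np.pi + np.arctan(y / x)
    theta = theta % TWO_PI
    return CylindricalPoint(r, float(theta), z)


def from_cylindrical(cp: CylindricalPoint | Sequence[float]) -> np.ndarray:
    """Cylindrical -> Cartesian, (r cos theta, r sin theta, z)."""
    if isinstance(cp, CylindricalPoint):
        r, theta, z = cp.r, cp.theta, cp.z
    else:
        r, theta, z = (float(v) for v in cp)
    return np.array([r * np.cos(theta), r * np.sin(theta), z])


def _theta_array(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorised branch table; equals arctan2 folded into [0, 2pi)."""
    return np.arctan2(y, x) % TWO_PI


def solid_to_cylindrical(solid: SolidModel) -> SolidModel:
    """Transform a Cartesian solid's control values to (r, theta, z).

    Theta is unwrapped along the circumferential control index so consecutive
    control angles are continuous (no 2*pi jumps); for periodic grids the
    wrapped trailing columns end up offset by exactly 2*pi, preserving a
    smooth seam.
    """
    if solid.coordinate_system != "cartesian":
        raise ValidationError("solid is not in Cartesian coordinates")
    pts = solid.grid.points
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    r = np.hypot(x, y)
    if np.any(r < 1e-9):
        raise ValidationError("control point on the long axis: theta undefined")
    theta = _theta_array(x, y)
    theta = np.unwrap(theta, axis=0)
    cyl = np.stack([r, theta, z], axis=-1)
    return SolidModel(ControlGrid3D(cyl), solid.knots_c, solid.knots_l,
                      solid.knots_r, coordinate_system="cylindrical")


# ---------------------------------------------------------------------------
# Wall point clouds
# ---------------------------------------------------------------------------


@dataclass
class WallPointCloud:
    """Slice/ring-indexed wall points for one wall of one cardiac phase.

    ``points`` is (N, 3) Cartesian mm; ``slice_index`` and ``ring_order``
    give each point's short-axis slice and position around its contour ring.
    """

    points: np.ndarray
    slice_index: np.ndarray
    ring_order: np.ndarray | None = None
    wall: str = "inner"
    phase: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.slice_index = np.asarray(self.slice_index, dtype=int)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError("points must be an (N, 3) array")
        if self.slice_index.shape != (self.points.shape[0],):
            raise ValidationError("slice_index must align with points")
        if self.wall not in ("inner", "outer"):
            raise ValidationError("wall must be 'inner' or 'outer'")
        for s in self.slices():
            n_s = int(np.sum(self.slice_index == s))
            if n_s < 4:
                raise ValidationError(f"slice {s} has only {n_s} points (< 4)")
        if self.ring_order is None:
            self._assign_ring_order()
        else:
            self.ring_order = np.asarray(self.ring_order, dtype=int)
            for s in self.slices():
                ro = np.sort(self.ring_order[self.slice_index == s])
                if not np.array_equal(ro, np.arange(ro.size)):
                    raise ValidationError(
                        f"ring_order in slice {s} is not a permutation 0..n-1"
                    )

    def _assign_ring_order(self) -> None:
        """Nearest-angle fallback ordering when segmentation order is absent."""
        ro = np.zeros(self.points.shape[0], dtype=int)
        theta = _theta_array(self.points[:, 0], self.points[:, 1])
        for s in self.slices():
            mask = self.slice_index == s
            ro[mask] = np.argsort(np.argsort(theta[mask]))
        self.ring_order = ro

    def slices(self) -> np.ndarray:
        """Slice indices ordered by mean z (apex-to-base stacking order)."""
        uniq = np.unique(self.slice_index)
        zbar = [self.points[self.slice_index == s, 2].mean() for s in uniq]
        return uniq[np.argsort(zbar)]

    def n_slices(self) -> int:
        return np.unique(self.slice_index).size

    def transformed(self, points: np.ndarray) -> "WallPointCloud":
        """Same indexing with new coordinates (tracked material points)."""
        return WallPointCloud(points, self.slice_index.copy(),
                              self.ring_order.copy(), self.wall, self.phase)


def parameterize_cloud(cloud: WallPointCloud) -> tuple[np.ndarray, np.ndarray]:
    """Per-point surface parameters (t, w), both in [0, 1].

    t: circumferential, the point's azimuth over 2*pi (so t wraps);
    w: longitudinal, normalized chord length along the z-ordered slice
    centroids (w=0 at the first slice, w=1 at the last).
    """
    pts = cloud.points
    t = _theta_array(pts[:, 0], pts[:, 1]) / TWO_PI
    order = cloud.slices()
    centroids = np.array([pts[cloud.slice_index == s].mean(axis=0) for s in order])
    for s in order:
        sl = pts[cloud.slice_index == s]
        if np.allclose(sl, sl[0]):
            raise ValidationError(f"slice {s} is degenerate (coincident points)")
    if order.size == 1:
        w_per_slice = {int(order[0]): 0.0}
    else:
        chords = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
        total = chords.sum()
        if total <= 0:
            raise ValidationError("slice centroids are coincident")
        cum = np.concatenate([[0.0], np.cumsum(chords)]) / total
        w_per_slice = {int(s): float(c) for s, c in zip(order, cum)}
    w = np.array([w_per_slice[int(s)] for s in cloud.slice_index])
    return t, w


# ---------------------------------------------------------------------------
# Surface fitting
# ---------------------------------------------------------------------------


@dataclass
class SurfaceFit:
    """Result of a least-squares surface fit."""

    surface: SurfaceModel
    rms: float
    params: tuple[np.ndarray, np.ndarray]  # per-point (t, w) used


def fit_surface(cloud: WallPointCloud, net_size: tuple[int, int],
                degrees: tuple[int, int] = (3, 3),
                params: tuple[np.ndarray, np.ndarray] | None = None,
                knots_w: KnotVector | None = None) -> SurfaceFit:
    """Least-squares periodic B-spline surface through a wall point cloud.

    Minimises ``sum_p || S(t_p, w_p) - x_p ||^2`` over the control net for a
    fixed per-point parameterization (from :func:`parameterize_cloud`, or the
    ``params`` of a reference phase when fitting tracked points of a later
    phase so that control-point differences are material displacements).

    ``net_size`` = (N, m+1): N unique circumferential columns (the stored net
    has N + k1 rows, wrapping the first k1) and m+1 longitudinal rows.
    """
    n_c, n_l = net_size
    k1, k2 = degrees
    if params is None:
        t, w = parameterize_cloud(cloud)
    else:
        t, w = params
    npts = cloud.points.shape[0]
    if npts < n_c * n_l:
        raise ValidationError(
            f"{npts} points cannot determine a {n_c}x{n_l} net"
        )
    knots_t = KnotVector.periodic_uniform(n_c, k1)
    if knots_w is None:
        knots_w = KnotVector.clamped_uniform(n_l, k2)
    A_t = basis_matrix(knots_t, t, fold=n_c)  # (P, n_c)
    A_w = basis_matrix(knots_w, w)            # (P, n_l)
    A = np.einsum("pi,pj->pij", A_t, A_w).reshape(npts, n_c * n_l)
    sol, _res, rank, _sv = np.linalg.lstsq(A, cloud.points, rcond=None)
    if rank < n_c * n_l:
        raise ValidationError(
            f"rank-deficient fit (rank {rank} < {n_c * n_l}); reduce the net "
            "size or supply more points"
        )
    unique_net = sol.reshape(n_c, n_l, 3)
    net = unique_net[np.arange(n_c + k1) % n_c]  # wrap first k1 columns
    surface = SurfaceModel(net, knots_t, knots_w)
    resid = A @ sol - cloud.points
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SurfaceFit(surface, rms, (t, w))


# ---------------------------------------------------------------------------
# Sweeping and solid fitting
# ---------------------------------------------------------------------------


@dataclass
class HexControlMesh:
    """Layered hexahedral control lattice between the two wall surfaces.

    Axis order: (circumferential, long-axis, radial); radial layer 0 is the
    inner (endocardial) net, the last layer the outer (epicardial) net.
    """

    grid: ControlGrid3D
    knots_c: KnotVector
    knots_l: KnotVector

    def __post_init__(self) -> None:
        if isinstance(self.grid, np.ndarray):
            self.grid = ControlGrid3D(self.grid)
        nc, nl, nr = self.grid.shape
        if nr < 2:
            raise ValidationError("hex mesh needs at least 2 radial layers")
        if self.knots_c.nbasis != nc or self.knots_l.nbasis != nl:
            raise ValidationError("knot vectors inconsistent with mesh shape")

    @property
    def radial_layers(self) -> int:
        return self.grid.shape[2]

    def min_cell_jacobian(self) -> float:
        """Smallest determinant of the trilinear cell map at cell centers.

        Positive everywhere means the control lattice is untangled.
        """
        g = self.grid.points
        dc = 0.25 * (g[1:, :-1, :-1] - g[:-1, :-1, :-1]
                     + g[1:, 1:, :-1] - g[:-1, 1:, :-1]
                     + g[1:, :-1, 1:] - g[:-1, :-1, 1:]
                     + g[1:, 1:, 1:] - g[:-1, 1:, 1:])
        dl = 0.25 * (g[:-1, 1:, :-1] - g[:-1, :-1, :-1]
                     + g[1:, 1:, :-1] - g[1:, :-1, :-1]
                     + g[:-1, 1:, 1:] - g[:-1, :-1, 1:]
                     + g[1:, 1:, 1:] - g[1:, :-1, 1:])
        dr = 0.25 * (g[:-1, :-1, 1:] - g[:-1, :-1, :-1]
                     + g[1:, :-1, 1:] - g[1:, :-1, :-1]
                     + g[:-1, 1:, 1:] - g[:-1, 1:, :-1]
                     + g[1:, 1:, 1:] - g[1:, 1:, :-1])
        dets = np.linalg.det(np.stack([dc, dl, dr], axis=-1))
        return float(dets.min())


def sweep_hex_mesh(inner: SurfaceModel, outer: SurfaceModel,
                   radial_layers: int = 4) -> HexControlMesh:
    """Sweep matched inner/outer control nets into a layered hexahedral mesh.

    Radial layer q (q = 0..L-1) is the linear blend
    ``(1 - q/(L-1)) * inner + (q/(L-1)) * outer`` of corresponding control
    points, so layer 0 reproduces the inner net exactly and the last layer the
    outer net.
    """
    if radial_layers < 2:
        raise ValidationError("radial_layers must be >= 2")
    if inner.net.shape != outer.net.shape:
        raise ValidationError("inner and outer nets have different sizes")
    for a, b, name in ((inner.knots_t, outer.knots_t, "circumferential"),
                       (inner.knots_w, outer.knots_w, "long-axis")):
        if a.degree != b.degree or a.form != b.form or \
                not np.allclose(a.values, b.values):
            raise ValidationError(f"{name} knot vectors differ between walls")
    q = np.linspace(0.0, 1.0, radial_layers)
    grid = (1.0 - q)[None, None, :, None] * inner.net[:, :, None, :] \
        + q[None, None, :, None] * outer.net[:, :, None, :]
    r_in = np.hypot(inner.net[..., 0], inner.net[..., 1])
    r_out = np.hypot(outer.net[..., 0], outer.net[..., 1])
    n_crossed = int(np.sum(r_in > r_out))
    if n_crossed:
        warnings.warn(
            f"walls cross at {n_crossed} matched control points "
            "(inner radius exceeds outer)", stacklevel=2)
    return HexControlMesh(ControlGrid3D(grid), inner.knots_t, inner.knots_w)


def fit_solid(mesh: HexControlMesh,
              knots: tuple[KnotVector, KnotVector, KnotVector] | None = None,
              degrees: tuple[int, int, int] | None = None,
              knot_method: str = "riesenfeld") -> SolidModel:
    """Trivariate solid adopting the swept hexahedral mesh as control grid.

    Circumferential/long-axis knots are inherited from the surfaces; the
    radial knot vector is built by :func:`make_knot_vector` over uniformly
    averaged layer parameters.  Explicit ``knots`` override everything.
    """
    nc, nl, nr = mesh.grid.shape
    if knots is not None:
        kc, kl, kr = knots
        return SolidModel(mesh.grid, kc, kl, kr)
    if degrees is None:
        degrees = (mesh.knots_c.degree, mesh.knots_l.degree,
                   min(3, nr - 1))
    k1, k2, k3 = degrees
    if k1 != mesh.knots_c.degree or k2 != mesh.knots_l.degree:
        raise ValidationError(
            "circumferential/long-axis degrees must match the swept surfaces"
        )
    if nr < k3 + 1:
        raise ValidationError(
            f"{nr} radial layers cannot carry a degree-{k3} radial basis"
        )
    layer_params = np.linspace(0.0, 1.0, nr)
    kr = make_knot_vector(layer_params, k3, knot_method)
    return SolidModel(mesh.grid, mesh.knots_c, mesh.knots_l, kr)


# ---------------------------------------------------------------------------
# Point-cloud I/O
# ---------------------------------------------------------------------------

_CSV_HEADER = ["x", "y", "z", "slice", "ring", "wall", "phase"]


def write_cloud_csv(cloud: WallPointCloud, path) -> None:
    """Write the cloud as CSV with header x,y,z,slice,ring,wall,phase."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(_CSV_HEADER)
        for p, s, r in zip(cloud.points, cloud.slice_index, cloud.ring_order):
            wr.writerow([repr(float(p[0])), repr(float(p[1])), repr(float(p[2])),
                         int(s), int(r), cloud.wall, cloud.phase])


def read_cloud_csv(path) -> list[WallPointCloud]:
    """Read clouds from CSV (one per wall/phase combination present).

    Plain whitespace- or comma-separated XYZ files (no header) are accepted;
    slices are then inferred by clustering z values at the largest gaps.
    """
    with open(path) as fh:
        first = fh.readline()
    if "x" in first.lower() and "slice" in first.lower():
        rows = []
        with open(path) as fh:
            rd = csv.DictReader(fh)
            for row in rd:
                rows.append(row)
        groups: dict[tuple[str, int], list] = {}
        for row in rows:
            key = (row["wall"], int(row["phase"]))
            groups.setdefault(key, []).append(row)
        clouds = []
        for (wall, phase), rws in sorted(groups.items()):
            pts = np.array([[float(r["x"]), float(r["y"]), float(r["z"])]
                            for r in rws])
            sl = np.array([int(r["slice"]) for r in rws])
            ring = np.array([int(r["ring"]) for r in rws])
            clouds.append(WallPointCloud(pts, sl, ring, wall, phase))
        return clouds
    # headerless XYZ
    pts = np.loadtxt(path, delimiter="," if "," in first else None)
    if pts.ndim != 2 or pts.shape[1] < 3:
        raise ValidationError("XYZ file must have three columns")
    pts = pts[:, :3]
    sl = _cluster_slices(pts[:, 2])
    return [WallPointCloud(pts, sl, None, "inner", 0)]


def _cluster_slices(z: np.ndarray) -> np.ndarray:
    """Assign slice indices by splitting sorted z at its dominant gaps."""
    order = np.argsort(z)
    zs = z[order]
    diffs = np.diff(zs)
    if diffs.size == 0 or diffs.max() <= 0:
        return np.zeros(z.size, dtype=int)
    threshold = 0.5 * diffs.max()
    labels_sorted = np.concatenate([[0], np.cumsum(diffs > threshold)])
    labels = np.empty(z.size, dtype=int)
    labels[order] = labels_sorted
    return labels
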
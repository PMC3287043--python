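"""Isogeometric strain and stress evaluation over B-spline solids.

The displacement field between two cardiac phases is carried by the same
trivariate B-spline basis as the geometry (isogeometric analysis): control
points of the displacement grid are the per-control-point motion between the
two fitted solids.  Pointwise, infinitesimal strain in Voigt form

    eps = [eps_x, eps_y, eps_z, gamma_xy, gamma_yz, gamma_xz]^T

is assembled from physical derivatives of the displacement components, which
are obtained from parametric derivatives through the inverse isoparametric
Jacobian.  Stress follows from the isotropic linear-elastic matrix,
``sigma = D eps``.

Engineering shears (gamma = sum of cross derivatives) are stored in the Voigt
vectors and halved when the symmetric tensor is reconstructed for principal
values.  Units: lengths/displacements mm, E and stress kPa, strain
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .splinecore import (
    KnotVector,
    SolidModel,
    ValidationError,
    basis_derivative_row,
    basis_row,
)

__all__ = [
    "MaterialParams",
    "DisplacementField",
    "StrainState",
    "StressState",
    "FieldGrid",
    "SingularMappingError",
    "elastic_matrix",
    "geometry_partial",
    "jacobian",
    "displacement_at",
    "basis_gradient_physical",
    "strain_at",
    "stress_at",
    "principal_values",
    "field_difference_displacements",
    "evaluate_field_grid",
    "integrate_volume",
    "export_vtk",
    "export_csv",
]


class SingularMappingError(ValueError):
    """The isoparametric map is (numerically) singular at a parameter point."""


# ---------------------------------------------------------------------------
# Material and states
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic linear-elastic material: modulus E (kPa), Poisson ratio mu.

    mu must be strictly below 0.5: the stiffness matrix is singular in the
    incompressible limit.  The default values (E = 11 kPa, mu = 0.49) are the
    standard passive-myocardium setting used throughout this package.
    """

    E: float = 11.0
    mu: float = 0.49

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValidationError("elasticity modulus E must be positive")
        if not 0.0 <= self.mu < 0.5:
            raise ValidationError(
                "Poisson ratio must satisfy 0 <= mu < 0.5 (incompressible limit)"
            )

    @property
    def H(self) -> float:
        """Shear-block coefficient (1 - 2*mu) / (2*(1 - mu))."""
        return (1.0 - 2.0 * self.mu) / (2.0 * (1.0 - self.mu))


def elastic_matrix(mat: MaterialParams) -> np.ndarray:
    """6x6 isotropic stiffness D (kPa) relating Voigt strain to stress.

    D = E(1-mu)/((1+mu)(1-2mu)) * [[A, 0], [0, H*I3]] where A has unit
    diagonal and mu/(1-mu) off-diagonal.
    """
    mu = mat.mu
    scale = mat.E * (1.0 - mu) / ((1.0 + mu) * (1.0 - 2.0 * mu))
    off = mu / (1.0 - mu)
    D = np.zeros((6, 6))
    D[:3, :3] = off
    np.fill_diagonal(D[:3, :3], 1.0)
    D[3:, 3:] = np.eye(3) * mat.H
    return scale * D


@dataclass(frozen=True)
class StrainState:
    """Voigt strain (eps_x, eps_y, eps_z, gamma_xy, gamma_yz, gamma_xz)."""

    voigt: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voigt, dtype=float)
        if v.shape != (6,) or not np.all(np.isfinite(v)):
            raise ValidationError("strain must be a finite 6-vector")
        object.__setattr__(self, "voigt", v)

    def tensor(self) -> np.ndarray:
        """Symmetric 3x3 tensor; engineering shears are halved."""
        ex, ey, ez, gxy, gyz, gxz = self.voigt
        return np.array([[ex, gxy / 2, gxz / 2],
                         [gxy / 2, ey, gyz / 2],
                         [gxz / 2, gyz / 2, ez]])


@dataclass(frozen=True)
class StressState:
    """Voigt stress (sigma_x, sigma_y, sigma_z, tau_xy, tau_yz, tau_xz), kPa."""

    voigt: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.voigt, dtype=float)
        if v.shape != (6,) or not np.all(np.isfinite(v)):
            raise ValidationError("stress must be a finite 6-vector")
        object.__setattr__(self, "voigt", v)

    def tensor(self) -> np.ndarray:
        sx, sy, sz, txy, tyz, txz = self.voigt
        return np.array([[sx, txy, txz],
                         [txy, sy, tyz],
                         [txz, tyz, sz]])


@dataclass
class DisplacementField:
    """Control-point displacement grid bound to a solid model (mm).

    ``data`` has the solid's control-grid shape (nc, nl, nr, 3); the x/y/z
    slabs are the ``dx``/``dy``/``dz`` component grids.
    """

    solid: SolidModel
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.solid.grid.points.shape:
            raise ValidationError(
                f"displacement grid {self.data.shape} does not match the "
                f"solid's control grid {self.solid.grid.points.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("displacement grid contains non-finite values")

    @property
    def dx(self) -> np.ndarray:
        return self.data[..., 0]

    @property
    def dy(self) -> np.ndarray:
        return self.data[..., 1]

    @property
    def dz(self) -> np.ndarray:
        return self.data[..., 2]


def field_difference_displacements(solid_t0: SolidModel,
                                   solid_t1: SolidModel) -> DisplacementField:
    """Displacement field between two phases as control-point differences.

    Both solids must share degrees, knot vectors and grid dimensions (fitted
    with a common configuration); the field is bound to ``solid_t0``.
    """
    if solid_t0.grid.points.shape != solid_t1.grid.points.shape:
        raise ValidationError("solids have different control-grid dimensions")
    for a, b, name in ((solid_t0.knots_c, solid_t1.knots_c, "circumferential"),
                       (solid_t0.knots_l, solid_t1.knots_l, "long-axis"),
                       (solid_t0.knots_r, solid_t1.knots_r, "radial")):
        if a.degree != b.degree or a.form != b.form \
                or not np.allclose(a.values, b.values):
            raise ValidationError(f"{name} knot vectors differ between phases")
    return DisplacementField(solid_t0, solid_t1.grid.points - solid_t0.grid.points)


# ---------------------------------------------------------------------------
# Derivatives and the isoparametric Jacobian
# ---------------------------------------------------------------------------

_DIRS = {"c": 0, "l": 1, "r": 2}


def _basis_rows(solid: SolidModel, t_c: float, t_l: float, t_r: float,
                deriv: int | None = None):
    """(row_c, row_l, row_r) with one direction optionally differentiated."""
    kvs = (solid.knots_c, solid.knots_l, solid.knots_r)
    ts = (t_c, t_l, t_r)
    return tuple(
        basis_derivative_row(kv, t) if deriv == ax else basis_row(kv, t)
        for ax, (kv, t) in enumerate(zip(kvs, ts))
    )


def geometry_partial(solid: SolidModel, direction: str,
                     t_c: float, t_l: float, t_r: float,
                     grid: np.ndarray | None = None) -> np.ndarray:
    """Partial derivative d(x,y,z)/d(t_direction) of the solid map.

    ``direction`` is 'c', 'l' or 'r'.  ``grid`` substitutes another control
    array of the same shape (e.g. a displacement grid) for the geometry.
    """
    if direction not in _DIRS:
        raise ValidationError("direction must be one of 'c', 'l', 'r'")
    g = solid.grid.points if grid is None else np.asarray(grid, dtype=float)
    rows = _basis_rows(solid, t_c, t_l, t_r, deriv=_DIRS[direction])
    return np.einsum("i,j,k,ijkd->d", *rows, g)


def jacobian(solid: SolidModel, t_c: float, t_l: float, t_r: float
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Isoparametric Jacobian J, its inverse and determinant at a point.

    J columns are the partials with respect to (t_c, t_l, t_r); rows are
    (x, y, z).  det J > 0 is expected for valid ventricular solids.
    """
    cols = [geometry_partial(solid, d, t_c, t_l, t_r) for d in ("c", "l", "r")]
    J = np.column_stack(cols)
    det = float(np.linalg.det(J))
    if abs(det) < 1e-12:
        raise SingularMappingError(
            f"singular isoparametric map at (t_c, t_l, t_r) = "
            f"({t_c:.6g}, {t_l:.6g}, {t_r:.6g}): det J = {det:.3e}"
        )
    return J, np.linalg.inv(J), det


def displacement_at(field: DisplacementField,
                    t_c: float, t_l: float, t_r: float) -> np.ndarray:
    """Continuous displacement (DX, DY, DZ) at a parameter point (mm)."""
    rows = _basis_rows(field.solid, t_c, t_l, t_r)
    return np.einsum("i,j,k,ijkd->d", *rows, field.data)


def basis_gradient_physical(solid: SolidModel, i: int, j: int, k: int,
                            t_c: float, t_l: float, t_r: float) -> np.ndarray:
    """Physical gradient (dN/dx, dN/dy, dN/dz) of one trivariate basis.

    The parametric gradient of N = N_i(t_c) N_j(t_l) N_k(t_r) is pushed
    through the isoparametric map by solving J^T g = grad_t N (equivalently
    the row-vector transform [dN/dx dN/dy dN/dz] = [dN/dt_c ...] J^-1).
    """
    bc = basis_row(solid.knots_c, t_c)
    bl = basis_row(solid.knots_l, t_l)
    br = basis_row(solid.knots_r, t_r)
    dc = basis_derivative_row(solid.knots_c, t_c)
    dl = basis_derivative_row(solid.knots_l, t_l)
    dr = basis_derivative_row(solid.knots_r, t_r)
    grad_t = np.array([
        dc[i] * bl[j] * br[k],
        bc[i] * dl[j] * br[k],
        bc[i] * bl[j] * dr[k],
    ])
    J, _Jinv, _det = jacobian(solid, t_c, t_l, t_r)
    return np.linalg.solve(J.T, grad_t)


def _displacement_gradient_physical(solid: SolidModel, field: DisplacementField,
                                    t_c: float, t_l: float, t_r: float
                                    ) -> np.ndarray:
    """3x3 matrix G with G[m, n] = d(D_m)/d(x_n)."""
    Gt = np.column_stack([
        geometry_partial(solid, d, t_c, t_l, t_r, grid=field.data)
        for d in ("c", "l", "r")
    ])  # Gt[m, a] = dD_m/dt_a
    _J, Jinv, _det = jacobian(solid, t_c, t_l, t_r)
    return Gt @ Jinv


def strain_at(solid: SolidModel, field: DisplacementField,
              t_c: float, t_l: float, t_r: float) -> StrainState:
    """Infinitesimal Voigt strain of the displacement field at a point.

    Normal components are the diagonal of the physical displacement gradient;
    shears are engineering shears (sums of cross derivatives).
    """
    if field.solid is not solid and \
            field.data.shape != solid.grid.points.shape:
        raise ValidationError("field is not compatible with this solid")
    G = _displacement_gradient_physical(solid, field, t_c, t_l, t_r)
    return StrainState(np.array([
        G[0, 0], G[1, 1], G[2, 2],
        G[0, 1] + G[1, 0],
        G[1, 2] + G[2, 1],
        G[0, 2] + G[2, 0],
    ]))


def stress_at(solid: SolidModel, field: DisplacementField, mat: MaterialParams,
              t_c: float, t_l: float, t_r: float) -> StressState:
    """Voigt stress sigma = D eps at a point (kPa)."""
    eps = strain_at(solid, field, t_c, t_l, t_r)
    return StressState(elastic_matrix(mat) @ eps.voigt)


def principal_values(state: StrainState | StressState
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Principal values (descending) and orthonormal principal directions.

    Eigen-decomposition of the symmetric 3x3 tensor; for strain the
    engineering shears are halved in the tensor reconstruction.
    """
    T = state.tensor()
    vals, vecs = np.linalg.eigh(T)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order]


# ---------------------------------------------------------------------------
# Field sampling and integration
# ---------------------------------------------------------------------------


@dataclass
class FieldGrid:
    """Row-major sample of all pointwise quantities over the parameter cube.

    Arrays are shaped (Nc, Nl, Nr, ...).  The circumferential samples exclude
    the seam duplicate (t in [0, 1)) when that direction is periodic.
    """

    params_c: np.ndarray
    params_l: np.ndarray
    params_r: np.ndarray
    position: np.ndarray            # (..., 3) mm
    displacement: np.ndarray        # (..., 3) mm
    strain: np.ndarray              # (..., 6)
    stress: np.ndarray              # (..., 6) kPa
    principal_strain: np.ndarray    # (..., 3) descending
    principal_stress: np.ndarray    # (..., 3) kPa, descending
    det_j: np.ndarray               # (...,) mm^3 per unit parameter volume

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.det_j.shape

    @property
    def eps_x(self) -> np.ndarray:
        return self.strain[..., 0]

    @property
    def sigma_x(self) -> np.ndarray:
        return self.stress[..., 0]


def evaluate_field_grid(solid: SolidModel, field: DisplacementField,
                        mat: MaterialParams,
                        resolution: tuple[int, int, int] = (16, 8, 4)
                        ) -> FieldGrid:
    """Sample position, strain, stress and principal values on a lattice.

    The lattice is a deterministic row-major product of per-direction
    parameter vectors; identical parameters reproduce pointwise calls
    bit-for-bit.
    """
    Nc, Nl, Nr = resolution
    if min(resolution) < 2:
        raise ValidationError("resolution must be >= 2 in every direction")
    periodic_c = solid.knots_c.form == "periodic"
    pc = np.linspace(0.0, 1.0, Nc, endpoint=not periodic_c)
    pl = np.linspace(0.0, 1.0, Nl)
    pr = np.linspace(0.0, 1.0, Nr)
    D = elastic_matrix(mat)
    pos = np.empty((Nc, Nl, Nr, 3))
    disp = np.empty((Nc, Nl, Nr, 3))
    strain = np.empty((Nc, Nl, Nr, 6))
    stress = np.empty((Nc, Nl, Nr, 6))
    p_eps = np.empty((Nc, Nl, Nr, 3))
    p_sig = np.empty((Nc, Nl, Nr, 3))
    detj = np.empty((Nc, Nl, Nr))
    for a, tc in enumerate(pc):
        for b, tl in enumerate(pl):
            for c, tr in enumerate(pr):
                pos[a, b, c] = solid.evaluate(tc, tl, tr)
                disp[a, b, c] = displacement_at(field, tc, tl, tr)
                eps = strain_at(solid, field, tc, tl, tr)
                sig = StressState(D @ eps.voigt)
                strain[a, b, c] = eps.voigt
                stress[a, b, c] = sig.voigt
                p_eps[a, b, c] = principal_values(eps)[0]
                p_sig[a, b, c] = principal_values(sig)[0]
                _J, _Ji, det = jacobian(solid, tc, tl, tr)
                detj[a, b, c] = det
    return FieldGrid(pc, pl, pr, pos, disp, strain, stress, p_eps, p_sig, detj)


def integrate_volume(solid: SolidModel, quadrature_order: int = 4) -> float:
    """Volume (mm^3) by Gauss-Legendre quadrature of det J over the cube.

    The rule is applied per knot span in each direction (the integrand is
    piecewise polynomial), with ``quadrature_order`` points per span.
    """
    if quadrature_order < 1:
        raise ValidationError("quadrature order must be >= 1")
    xg, wg = np.polynomial.legendre.leggauss(quadrature_order)

    def span_points(kv: KnotVector) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = kv.domain
        breaks = np.unique(kv.values[(kv.values >= lo) & (kv.values <= hi)])
        pts, wts = [], []
        for a, b in zip(breaks[:-1], breaks[1:]):
            half = 0.5 * (b - a)
            pts.append(0.5 * (a + b) + half * xg)
            wts.append(half * wg)
        return np.concatenate(pts), np.concatenate(wts)

    pc, wc = span_points(solid.knots_c)
    pl, wl = span_points(solid.knots_l)
    pr, wr = span_points(solid.knots_r)
    total = 0.0
    for tc, wtc in zip(pc, wc):
        for tl, wtl in zip(pl, wl):
            for tr, wtr in zip(pr, wr):
                _J, _Ji, det = jacobian(solid, tc, tl, tr)
                if det < 0:
                    raise SingularMappingError(
                        f"negative Jacobian determinant {det:.3e} at "
                        f"({tc:.4g}, {tl:.4g}, {tr:.4g})"
                    )
                total += wtc * wtl * wtr * det
    return float(total)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_vtk(grid: FieldGrid, path) -> None:
    """Write the sampled fields as a legacy ASCII VTK structured grid.

    Point-data arrays: displacement, strain6, stress6, principal_strain,
    principal_stress, epsx, sigx, detJ.  VTK structured grids vary the first
    index fastest, so arrays are emitted transposed to (Nr, Nl, Nc) order.
    """
    Nc, Nl, Nr = grid.shape
    npts = Nc * Nl * Nr

    def flat(arr: np.ndarray) -> np.ndarray:
        # (Nc, Nl, Nr, ...) -> rows with the c-index varying fastest
        moved = np.moveaxis(arr, (0, 1, 2), (2, 1, 0))
        return moved.reshape(npts, -1)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("lvsolid field sample\nASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {Nc} {Nl} {Nr}\n")
        fh.write(f"POINTS {npts} double\n")
        for row in flat(grid.position):
            fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
        fh.write(f"POINT_DATA {npts}\n")

        def write_array(name: str, arr: np.ndarray, ncomp: int) -> None:
            if ncomp == 3:
                fh.write(f"VECTORS {name} double\n")
                for row in flat(arr):
                    fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
            else:
                fh.write(f"SCALARS {name} double {ncomp}\n")
                fh.write("LOOKUP_TABLE default\n")
                for row in flat(arr):
                    fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")

        write_array("displacement", grid.displacement, 3)
        write_array("strain6", grid.strain, 6)
        write_array("stress6", grid.stress, 6)
        write_array("principal_strain", grid.principal_strain, 3)
        write_array("principal_stress", grid.principal_stress, 3)
        write_array("epsx", grid.eps_x[..., None], 1)
        write_array("sigx", grid.sigma_x[..., None], 1)
        write_array("detJ", grid.det_j[..., None], 1)


def export_csv(grid: FieldGrid, path) -> None:
    """Flat CSV export: parameters, position, all field components."""
    header = (
        "t_c,t_l,t_r,x,y,z,ux,uy,uz,"
        "eps_x,eps_y,eps_z,gamma_xy,gamma_yz,gamma_xz,"
        "sig_x,sig_y,sig_z,tau_xy,tau_yz,tau_xz,"
        "e1,e2,e3,s1,s2,s3,detJ"
    )
    Nc, Nl, Nr = grid.shape
    rows = []
    for a in range(Nc):
        for b in range(Nl):
            for c in range(Nr):
                rows.append(np.concatenate([
                    [grid.params_c[a], grid.params_l[b], grid.params_r[c]],
                    grid.position[a, b, c], grid.displacement[a, b, c],
                    grid.strain[a, b, c], grid.stress[a, b, c],
                    grid.principal_strain[a, b, c],
                    grid.principal_stress[a, b, c],
                    [grid.det_j[a, b, c]],
                ]))
    np.savetxt(path, np.array(rows), delimiter=",", header=header, comments="")
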
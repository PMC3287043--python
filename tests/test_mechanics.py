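"""Isogeometric mechanics: elastic matrix, Jacobian transform, patch tests
for strain exactness, constitutive consistency, principal values, field
sampling and volume quadrature."""

import numpy as np
import pytest

from conftest import make_cylinder_cloud, make_identity_cube, make_random_solid
from lvsolid.geometry import fit_solid, fit_surface, sweep_hex_mesh
from lvsolid.mechanics import (
    DisplacementField,
    MaterialParams,
    SingularMappingError,
    StrainState,
    StressState,
    basis_gradient_physical,
    displacement_at,
    elastic_matrix,
    evaluate_field_grid,
    export_csv,
    export_vtk,
    field_difference_displacements,
    geometry_partial,
    integrate_volume,
    jacobian,
    principal_values,
    strain_at,
    stress_at,
)
from lvsolid.splinecore import (
    ControlGrid3D,
    KnotVector,
    SolidModel,
    ValidationError,
    basis_value,
)


def affine_field(solid: SolidModel, A: np.ndarray,
                 b=(0.0, 0.0, 0.0)) -> DisplacementField:
    """Displacement field interpolating u(x) = A x + b exactly.

    Because the displacement shares the geometry basis, setting control
    displacements to A p + b reproduces the affine field pointwise (linear
    precision of the tensor-product basis).
    """
    g = solid.grid.points
    data = g @ np.asarray(A, dtype=float).T + np.asarray(b, dtype=float)
    return DisplacementField(solid, data)


def scaled_solid(factors) -> SolidModel:
    cube = make_identity_cube()
    g = cube.grid.points * np.asarray(factors, dtype=float)
    return SolidModel(ControlGrid3D(g), cube.knots_c, cube.knots_l,
                      cube.knots_r)


class TestElasticMatrix:
    def test_mu_zero_is_diagonal(self):
        D = elastic_matrix(MaterialParams(E=7.0, mu=0.0))
        np.testing.assert_allclose(D, np.diag([7, 7, 7, 3.5, 3.5, 3.5]),
                                   atol=1e-12)

    @pytest.mark.parametrize("E,mu", [(11.0, 0.49), (1.0, 0.3), (50.0, 0.0),
                                      (5.0, 0.45)])
    def test_symmetric_positive_definite(self, E, mu):
        D = elastic_matrix(MaterialParams(E=E, mu=mu))
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert np.min(np.linalg.eigvalsh(D)) > 0

    def test_leading_scalar_and_shear_block(self):
        E, mu = 11.0, 0.49
        D = elastic_matrix(MaterialParams(E=E, mu=mu))
        scale = E * (1 - mu) / ((1 + mu) * (1 - 2 * mu))  # independent arithmetic
        H = (1 - 2 * mu) / (2 * (1 - mu))
        assert D[0, 0] == pytest.approx(scale)
        assert D[0, 1] == pytest.approx(scale * mu / (1 - mu))
        assert D[3, 3] == pytest.approx(scale * H)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValidationError):
            MaterialParams(E=11.0, mu=0.5)
        with pytest.raises(ValidationError):
            MaterialParams(E=-1.0, mu=0.3)


class TestGeometryPartialAndJacobian:
    def test_identity_cube_partials(self, identity_cube):
        np.testing.assert_allclose(
            geometry_partial(identity_cube, "c", 0.4, 0.5, 0.6), [1, 0, 0],
            atol=1e-13)
        np.testing.assert_allclose(
            geometry_partial(identity_cube, "l", 0.4, 0.5, 0.6), [0, 1, 0],
            atol=1e-13)
        np.testing.assert_allclose(
            geometry_partial(identity_cube, "r", 0.4, 0.5, 0.6), [0, 0, 1],
            atol=1e-13)

    def test_affine_image_partials_are_matrix_columns(self, identity_cube):
        rng = np.random.default_rng(0)
        A = np.eye(3) + 0.3 * rng.normal(size=(3, 3))
        g = identity_cube.grid.points @ A.T
        solid = SolidModel(ControlGrid3D(g), identity_cube.knots_c,
                           identity_cube.knots_l, identity_cube.knots_r)
        for d, col in zip(("c", "l", "r"), A.T):
            np.testing.assert_allclose(
                geometry_partial(solid, d, 0.3, 0.7, 0.5), col, atol=1e-12)

    def test_finite_difference_oracle(self, random_solid):
        rng = np.random.default_rng(1)
        h = 1e-6
        for _ in range(100):
            t, w, u = rng.uniform(2 * h, 1 - 2 * h, 3)
            for d, delta in (("c", (h, 0, 0)), ("l", (0, h, 0)),
                             ("r", (0, 0, h))):
                fd = (random_solid.evaluate(t + delta[0], w + delta[1],
                                            u + delta[2])
                      - random_solid.evaluate(t - delta[0], w - delta[1],
                                              u - delta[2])) / (2 * h)
                an = geometry_partial(random_solid, d, t, w, u)
                np.testing.assert_allclose(an, fd, rtol=1e-5, atol=1e-7)

    def test_jacobian_identity_and_scaling(self, identity_cube):
        J, Jinv, det = jacobian(identity_cube, 0.5, 0.5, 0.5)
        np.testing.assert_allclose(J, np.eye(3), atol=1e-13)
        assert det == pytest.approx(1.0)
        _J, _Ji, det = jacobian(scaled_solid((2, 3, 4)), 0.5, 0.5, 0.5)
        assert det == pytest.approx(24.0)

    def test_jacobian_inverse(self, random_solid):
        rng = np.random.default_rng(2)
        for t, w, u in rng.uniform(0.05, 0.95, (20, 3)):
            J, Jinv, det = jacobian(random_solid, t, w, u)
            np.testing.assert_allclose(J @ Jinv, np.eye(3), atol=1e-10)
            assert det > 0

    def test_singular_mapping_named_in_error(self):
        g = np.zeros((2, 2, 2, 3))  # degenerate map
        kv = KnotVector.clamped_uniform(2, 1)
        solid = SolidModel(ControlGrid3D(g), kv, kv, kv)
        with pytest.raises(SingularMappingError, match="0.5"):
            jacobian(solid, 0.5, 0.5, 0.5)


class TestDisplacement:
    def test_constant_field_everywhere(self, random_solid):
        fld = affine_field(random_solid, np.zeros((3, 3)), (1.0, -2.0, 0.5))
        for t, w, u in [(0, 0, 0), (0.5, 0.3, 0.8), (1, 1, 1)]:
            np.testing.assert_allclose(displacement_at(fld, t, w, u),
                                       [1, -2, 0.5], atol=1e-13)

    def test_direct_summation_oracle(self, random_solid):
        rng = np.random.default_rng(3)
        data = rng.normal(size=random_solid.grid.points.shape)
        fld = DisplacementField(random_solid, data)
        kvs = (random_solid.knots_c, random_solid.knots_l, random_solid.knots_r)
        for t, w, u in rng.uniform(0, 1, (20, 3)):
            expect = np.zeros(3)
            for i in range(data.shape[0]):
                for j in range(data.shape[1]):
                    for k in range(data.shape[2]):
                        expect += data[i, j, k] * basis_value(kvs[0], i, t) * \
                            basis_value(kvs[1], j, w) * basis_value(kvs[2], k, u)
            np.testing.assert_allclose(displacement_at(fld, t, w, u), expect,
                                       atol=1e-12)

    def test_shape_mismatch_rejected(self, random_solid):
        with pytest.raises(ValidationError):
            DisplacementField(random_solid, np.zeros((2, 2, 2, 3)))


class TestBasisGradientPhysical:
    def test_identity_cube_equals_parametric(self, identity_cube):
        from lvsolid.splinecore import basis_derivative_row, basis_row
        t, w, u = 0.3, 0.6, 0.4
        for i in range(2):
            g = basis_gradient_physical(identity_cube, i, 1, 0, t, w, u)
            expect = np.array([
                basis_derivative_row(identity_cube.knots_c, t)[i]
                * basis_row(identity_cube.knots_l, w)[1]
                * basis_row(identity_cube.knots_r, u)[0],
                basis_row(identity_cube.knots_c, t)[i]
                * basis_derivative_row(identity_cube.knots_l, w)[1]
                * basis_row(identity_cube.knots_r, u)[0],
                basis_row(identity_cube.knots_c, t)[i]
                * basis_row(identity_cube.knots_l, w)[1]
                * basis_derivative_row(identity_cube.knots_r, u)[0],
            ])
            np.testing.assert_allclose(g, expect, atol=1e-12)

    def test_scaled_cube_chain_rule(self):
        solid = scaled_solid((2, 4, 5))
        g_phys = basis_gradient_physical(solid, 1, 0, 1, 0.3, 0.6, 0.4)
        cube = make_identity_cube()
        g_param = basis_gradient_physical(cube, 1, 0, 1, 0.3, 0.6, 0.4)
        np.testing.assert_allclose(g_phys, g_param / np.array([2, 4, 5]),
                                   atol=1e-12)

    def test_gradients_sum_to_zero(self, random_solid):
        nc, nl, nr = random_solid.grid.shape
        total = np.zeros(3)
        for i in range(nc):
            for j in range(nl):
                for k in range(nr):
                    total += basis_gradient_physical(random_solid, i, j, k,
                                                     0.37, 0.52, 0.61)
        np.testing.assert_allclose(total, 0.0, atol=1e-10)


class TestStrainStress:
    def test_rigid_translation_zero_strain(self, random_solid):
        fld = affine_field(random_solid, np.zeros((3, 3)), (3.0, -1.0, 2.0))
        for t, w, u in np.random.default_rng(4).uniform(0.02, 0.98, (25, 3)):
            eps = strain_at(random_solid, fld, t, w, u)
            assert np.max(np.abs(eps.voigt)) < 1e-10

    def test_uniform_dilation_patch(self, random_solid):
        alpha = 0.03
        fld = affine_field(random_solid, alpha * np.eye(3))
        for t, w, u in np.random.default_rng(5).uniform(0.02, 0.98, (25, 3)):
            eps = strain_at(random_solid, fld, t, w, u)
            np.testing.assert_allclose(
                eps.voigt, [alpha, alpha, alpha, 0, 0, 0], atol=1e-8)

    def test_simple_shear_patch(self, random_solid):
        beta = 0.02
        A = np.zeros((3, 3))
        A[0, 1] = beta  # u = beta * y
        fld = affine_field(random_solid, A)
        for t, w, u in np.random.default_rng(6).uniform(0.02, 0.98, (25, 3)):
            eps = strain_at(random_solid, fld, t, w, u)
            np.testing.assert_allclose(eps.voigt, [0, 0, 0, beta, 0, 0],
                                       atol=1e-8)

    def test_finite_difference_chain_rule_oracle(self, random_solid):
        """Strain vs an independent route: parametric FD of displacement and
        geometry, assembled through the FD Jacobian inverse."""
        rng = np.random.default_rng(7)
        data = 0.05 * rng.normal(size=random_solid.grid.points.shape)
        fld = DisplacementField(random_solid, data)
        h = 1e-6
        for t, w, u in rng.uniform(0.05, 0.95, (50, 3)):
            Dt = np.column_stack([
                (displacement_at(fld, t + h, w, u)
                 - displacement_at(fld, t - h, w, u)) / (2 * h),
                (displacement_at(fld, t, w + h, u)
                 - displacement_at(fld, t, w - h, u)) / (2 * h),
                (displacement_at(fld, t, w, u + h)
                 - displacement_at(fld, t, w, u - h)) / (2 * h),
            ])
            Xt = np.column_stack([
                (random_solid.evaluate(t + h, w, u)
                 - random_solid.evaluate(t - h, w, u)) / (2 * h),
                (random_solid.evaluate(t, w + h, u)
                 - random_solid.evaluate(t, w - h, u)) / (2 * h),
                (random_solid.evaluate(t, w, u + h)
                 - random_solid.evaluate(t, w, u - h)) / (2 * h),
            ])
            G = Dt @ np.linalg.inv(Xt)
            expect = np.array([G[0, 0], G[1, 1], G[2, 2],
                               G[0, 1] + G[1, 0], G[1, 2] + G[2, 1],
                               G[0, 2] + G[2, 0]])
            eps = strain_at(random_solid, fld, t, w, u).voigt
            np.testing.assert_allclose(eps, expect, rtol=1e-5, atol=1e-7)

    def test_stress_is_elastic_matrix_times_strain(self, random_solid):
        rng = np.random.default_rng(8)
        data = 0.05 * rng.normal(size=random_solid.grid.points.shape)
        fld = DisplacementField(random_solid, data)
        mat = MaterialParams()
        D = elastic_matrix(mat)
        for t, w, u in rng.uniform(0.05, 0.95, (10, 3)):
            eps = strain_at(random_solid, fld, t, w, u)
            sig = stress_at(random_solid, fld, mat, t, w, u)
            np.testing.assert_array_equal(sig.voigt, D @ eps.voigt)

    def test_uniaxial_stress_mu_zero(self, identity_cube):
        alpha = 0.01
        A = np.zeros((3, 3))
        A[0, 0] = alpha
        fld = affine_field(identity_cube, A)
        sig = stress_at(identity_cube, fld, MaterialParams(E=11.0, mu=0.0),
                        0.5, 0.5, 0.5)
        np.testing.assert_allclose(sig.voigt, [11 * alpha, 0, 0, 0, 0, 0],
                                   atol=1e-12)

    def test_hydrostatic_stress_bulk_modulus_oracle(self, identity_cube):
        E, mu, alpha = 11.0, 0.3, 0.02
        fld = affine_field(identity_cube, alpha * np.eye(3))
        sig = stress_at(identity_cube, fld, MaterialParams(E=E, mu=mu),
                        0.5, 0.5, 0.5).voigt
        K = E / (3 * (1 - 2 * mu))  # independent closed-form bulk modulus
        np.testing.assert_allclose(sig[:3], 3 * K * alpha, rtol=1e-12)
        np.testing.assert_allclose(sig[3:], 0.0, atol=1e-12)


class TestPrincipalValues:
    def test_diagonal_tensor(self):
        vals, vecs = principal_values(
            StrainState(np.array([3.0, 2.0, 1.0, 0, 0, 0])))
        np.testing.assert_allclose(vals, [3, 2, 1])
        np.testing.assert_allclose(np.abs(vecs), np.eye(3), atol=1e-12)

    def test_pure_shear(self):
        g = 0.04
        vals, _ = principal_values(
            StrainState(np.array([0, 0, 0, 2 * g, 0, 0])))
        np.testing.assert_allclose(vals, [g, 0, -g], atol=1e-14)

    def test_stress_shear_not_halved(self):
        tau = 5.0
        vals, _ = principal_values(
            StressState(np.array([0, 0, 0, tau, 0, 0])))
        np.testing.assert_allclose(vals, [tau, 0, -tau], atol=1e-12)

    def test_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            v = rng.normal(size=6)
            state = StrainState(v)
            T = state.tensor()
            # roots of det(T - x I) computed independently
            c2 = -np.trace(T)
            c1 = 0.5 * (np.trace(T) ** 2 - np.trace(T @ T))
            c0 = -np.linalg.det(T)
            roots = np.sort(np.real(np.roots([1.0, c2, c1, c0])))[::-1]
            vals, vecs = principal_values(state)
            np.testing.assert_allclose(vals, roots, atol=1e-10)
            np.testing.assert_allclose(vecs.T @ vecs, np.eye(3), atol=1e-10)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(10)
        from scipy.spatial.transform import Rotation
        v = rng.normal(size=6)
        state = StrainState(v)
        vals, _ = principal_values(state)
        R = Rotation.random(random_state=3).as_matrix()
        T_rot = R @ state.tensor() @ R.T
        rot_state = StrainState(np.array([
            T_rot[0, 0], T_rot[1, 1], T_rot[2, 2],
            2 * T_rot[0, 1], 2 * T_rot[1, 2], 2 * T_rot[0, 2]]))
        vals_rot, _ = principal_values(rot_state)
        np.testing.assert_allclose(vals_rot, vals, atol=1e-10)


class TestFieldDifference:
    def test_identical_solids_zero_field(self, random_solid):
        fld = field_difference_displacements(random_solid, random_solid)
        assert np.all(fld.data == 0)

    def test_translated_solid_constant_field(self, random_solid):
        g = random_solid.grid.points + np.array([1.0, 2.0, -3.0])
        other = SolidModel(ControlGrid3D(g), random_solid.knots_c,
                           random_solid.knots_l, random_solid.knots_r)
        fld = field_difference_displacements(random_solid, other)
        np.testing.assert_allclose(fld.data,
                                   np.broadcast_to([1, 2, -3], fld.data.shape))

    def test_scaled_solid_uniform_strain(self, random_solid):
        alpha = 0.04
        g = (1 + alpha) * random_solid.grid.points
        other = SolidModel(ControlGrid3D(g), random_solid.knots_c,
                           random_solid.knots_l, random_solid.knots_r)
        fld = field_difference_displacements(random_solid, other)
        for t, w, u in np.random.default_rng(11).uniform(0.1, 0.9, (10, 3)):
            eps = strain_at(random_solid, fld, t, w, u)
            np.testing.assert_allclose(eps.voigt,
                                       [alpha, alpha, alpha, 0, 0, 0],
                                       atol=1e-9)

    def test_topology_mismatch_rejected(self, random_solid):
        other = make_random_solid(12, shape=(6, 4, 4))
        with pytest.raises(ValidationError):
            field_difference_displacements(random_solid, other)


class TestFieldGridAndVolume:
    def test_zero_field_all_zero(self, random_solid):
        fld = DisplacementField(random_solid,
                                np.zeros_like(random_solid.grid.points))
        grid = evaluate_field_grid(random_solid, fld, MaterialParams(), (3, 3, 3))
        assert np.all(grid.strain == 0) and np.all(grid.stress == 0)

    def test_minimal_resolution_eight_samples(self, random_solid):
        fld = DisplacementField(random_solid,
                                np.zeros_like(random_solid.grid.points))
        grid = evaluate_field_grid(random_solid, fld, MaterialParams(), (2, 2, 2))
        assert grid.shape == (2, 2, 2)
        assert grid.position.reshape(-1, 3).shape[0] == 8

    def test_lattice_matches_pointwise_calls(self, random_solid):
        rng = np.random.default_rng(12)
        data = 0.05 * rng.normal(size=random_solid.grid.points.shape)
        fld = DisplacementField(random_solid, data)
        mat = MaterialParams()
        grid = evaluate_field_grid(random_solid, fld, mat, (3, 3, 3))
        for a, t in enumerate(grid.params_c):
            for b, w in enumerate(grid.params_l):
                for c, u in enumerate(grid.params_r):
                    eps = strain_at(random_solid, fld, t, w, u)
                    assert np.array_equal(grid.strain[a, b, c], eps.voigt)
                    sig = stress_at(random_solid, fld, mat, t, w, u)
                    assert np.array_equal(grid.stress[a, b, c], sig.voigt)

    def test_unit_cube_volume(self, identity_cube):
        assert integrate_volume(identity_cube, 4) == pytest.approx(1.0)

    def test_scaled_cube_volume(self):
        assert integrate_volume(scaled_solid((2, 3, 4)), 4) == pytest.approx(24.0)

    def test_annulus_volume_within_one_percent(self):
        r_i, r_o, h = 20.0, 30.0, 50.0
        fi = fit_surface(make_cylinder_cloud(r_i, height=h), (8, 4))
        fo = fit_surface(make_cylinder_cloud(r_o, height=h, wall="outer"),
                         (8, 4))
        solid = fit_solid(sweep_hex_mesh(fi.surface, fo.surface, 4))
        vol = integrate_volume(solid, 4)
        expect = np.pi * (r_o**2 - r_i**2) * h
        assert abs(vol - expect) / expect < 0.01
        # quadrature stability: order 4 -> 6 changes the value by < 0.1%
        vol6 = integrate_volume(solid, 6)
        assert abs(vol6 - vol) / vol < 1e-3

    def test_negative_jacobian_rejected(self):
        cube = make_identity_cube()
        g = cube.grid.points.copy()
        g[..., 0] *= -1  # mirrored: det J < 0
        solid = SolidModel(ControlGrid3D(g), cube.knots_c, cube.knots_l,
                           cube.knots_r)
        with pytest.raises(SingularMappingError):
            integrate_volume(solid, 2)


class TestExport:
    def test_vtk_and_csv_outputs(self, tmp_path, random_solid):
        rng = np.random.default_rng(13)
        data = 0.05 * rng.normal(size=random_solid.grid.points.shape)
        fld = DisplacementField(random_solid, data)
        grid = evaluate_field_grid(random_solid, fld, MaterialParams(), (3, 3, 2))
        vtk_path = tmp_path / "fields.vtk"
        export_vtk(grid, vtk_path)
        text = vtk_path.read_text()
        assert text.startswith("# vtk DataFile Version 3.0")
        assert "DIMENSIONS 3 3 2" in text
        for name in ("displacement", "strain6", "stress6", "principal_strain",
                     "principal_stress", "epsx", "sigx", "detJ"):
            assert name in text
        csv_path = tmp_path / "fields.csv"
        export_csv(grid, csv_path)
        arr = np.loadtxt(csv_path, delimiter=",", skiprows=1)
        assert arr.shape == (18, 28)
        # first row corresponds to parameters (0, 0, 0)
        np.testing.assert_allclose(arr[0, :3], 0.0)
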
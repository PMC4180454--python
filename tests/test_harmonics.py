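"""Real spherical-harmonic fitting, first-order ellipsoid, PDM sampling."""

import numpy as np
import pytest

from lvshape.harmonics import (
    HarmonicsError,
    SpharmCoeffs,
    first_order_ellipsoid,
    fit_spharm,
    fit_spharm_values,
    n_coeffs,
    real_sh_basis,
    sample_pdm,
    sh_index,
)
from lvshape.meshing import SurfaceMesh
from lvshape.sphere import icosphere, sphere_to_angles, spherical_parameterize


def analytic_param_coeffs(semi=(30.0, 20.0, 10.0), degree=6, subdivision=16):
    """SPHARM fit of an ellipsoid under its natural parameterization
    x = a*u_x, y = b*u_y, z = c*u_z (exactly degree-1)."""
    verts, _ = icosphere(subdivision)
    theta, phi = sphere_to_angles(verts)
    pts = verts * np.asarray(semi)
    return fit_spharm_values(pts, theta, phi, degree)


class TestBasis:
    def test_orthonormal_under_gauss_legendre_quadrature(self):
        """Exact product quadrature: Gauss-Legendre in cos(colatitude) x
        uniform longitudes integrates degree <= 8 products exactly."""
        x, wx = np.polynomial.legendre.leggauss(30)
        nphi = 40
        phi1 = 2 * np.pi * np.arange(nphi) / nphi
        theta = np.repeat(np.arccos(x), nphi)
        phi = np.tile(phi1, len(x))
        w = np.repeat(wx, nphi) * (2 * np.pi / nphi)
        B = real_sh_basis(theta, phi, 4)
        gram = (B * w[:, None]).T @ B
        assert np.allclose(gram, np.eye(n_coeffs(4)), atol=1e-10)

    def test_degree1_encodes_cartesian_directions(self):
        verts, _ = icosphere(10)
        theta, phi = sphere_to_angles(verts)
        B = real_sh_basis(theta, phi, 1)
        c = np.sqrt(3 / (4 * np.pi))
        assert np.allclose(B[:, sh_index(1, 1)], c * verts[:, 0], atol=1e-12)
        assert np.allclose(B[:, sh_index(1, -1)], c * verts[:, 1], atol=1e-12)
        assert np.allclose(B[:, sh_index(1, 0)], c * verts[:, 2], atol=1e-12)


class TestFit:
    def test_unit_sphere_degree1(self):
        """The degree-1 reconstruction of a parameterized unit sphere is a
        sphere of radius ~1 (the area-preserving map may shear within
        latitudes, so the pointwise residual is only loosely bounded)."""
        v, f = icosphere(8)
        mesh = SurfaceMesh(v, f)
        param = spherical_parameterize(mesh, max_iter=1500)
        c = fit_spharm(mesh, param, 1)
        recon = c.evaluate(param.theta, param.phi)
        radii = np.linalg.norm(recon - c.centroid, axis=1)
        assert abs(radii.mean() - 1.0) < 0.01
        ell = first_order_ellipsoid(c)
        assert np.allclose(ell.semi_lengths, 1.0, rtol=0.01)
        assert c.rms_residual < 0.1

    def test_degree0_collapses_to_centroid(self, tube_mesh, tube_param):
        c = fit_spharm(tube_mesh, tube_param, 0)
        recon = c.evaluate(tube_param.theta[:5], tube_param.phi[:5])
        assert np.allclose(recon, recon[0])
        assert np.allclose(recon[0], tube_mesh.vertices.mean(axis=0), atol=2.0)

    def test_residual_monotone_in_degree(self, tube_mesh, tube_param):
        rms = [fit_spharm(tube_mesh, tube_param, L).rms_residual
               for L in (1, 2, 4, 8, 12)]
        assert all(a >= b for a, b in zip(rms, rms[1:]))

    def test_too_few_vertices_rejected(self):
        v, f = icosphere(1)  # 12 vertices
        mesh = SurfaceMesh(v, f)
        param = spherical_parameterize(mesh, max_iter=50)
        with pytest.raises(HarmonicsError, match="coefficients"):
            fit_spharm(mesh, param, 4)  # needs 25


class TestFirstOrderEllipsoid:
    def test_sphere_has_equal_semi_lengths(self):
        c = analytic_param_coeffs(semi=(1.0, 1.0, 1.0), degree=2)
        ell = first_order_ellipsoid(c)
        assert ell.semi_lengths.max() / ell.semi_lengths.min() < 1.01

    def test_axis_aligned_321_ratios(self):
        ell = first_order_ellipsoid(analytic_param_coeffs())
        ratios = ell.semi_lengths / ell.semi_lengths[2]
        assert np.allclose(ratios, [3.0, 2.0, 1.0], rtol=0.02)
        # axes aligned with coordinate axes
        assert abs(ell.axes[0] @ [1, 0, 0]) > 0.999
        assert abs(ell.axes[2] @ [0, 0, 1]) > 0.999

    def test_rotated_ellipsoid_axes_recovered(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        verts, _ = icosphere(16)
        theta, phi = sphere_to_angles(verts)
        pts = (verts * np.array([30.0, 20.0, 10.0])) @ R.T
        c = fit_spharm_values(pts, theta, phi, 4)
        ell = first_order_ellipsoid(c)
        assert abs(ell.axes[0] @ R[:, 0]) > 0.999
        assert np.allclose(ell.semi_lengths / ell.semi_lengths[2], [3, 2, 1], rtol=0.02)

    def test_zero_degree1_rejected(self):
        coeffs = np.zeros((3, n_coeffs(2)))
        coeffs[:, 0] = 1.0
        with pytest.raises(HarmonicsError, match="rank deficient"):
            first_order_ellipsoid(SpharmCoeffs(2, coeffs))


class TestSamplePDM:
    @pytest.mark.parametrize("n,expected", [(1, 12), (10, 1002)])
    def test_point_counts(self, n, expected, tube_coeffs):
        surf = sample_pdm(tube_coeffs, n)
        assert surf.n_points == expected

    def test_sphere_coefficients_sample_to_unit_radius(self):
        c = analytic_param_coeffs(semi=(1.0, 1.0, 1.0), degree=2)
        surf = sample_pdm(c, 6)
        assert np.allclose(np.linalg.norm(surf.points, axis=1), 1.0, atol=1e-3)

    def test_invalid_subdivision(self, tube_coeffs):
        with pytest.raises(HarmonicsError):
            sample_pdm(tube_coeffs, 0)

    def test_pdm_matches_analytic_evaluation(self):
        """Oracle equivalence: sampled PDM of an analytically parameterized
        ellipsoid equals direct analytic evaluation within 1 % of the longest
        semi-axis."""
        c = analytic_param_coeffs(degree=6)
        surf = sample_pdm(c, 10)
        analytic = (
            np.column_stack([
                np.sin(surf.theta) * np.cos(surf.phi) * 30.0,
                np.sin(surf.theta) * np.sin(surf.phi) * 20.0,
                np.cos(surf.theta) * 10.0,
            ])
        )
        err = np.linalg.norm(surf.points - analytic, axis=1).max()
        assert err < 0.01 * 30.0

    def test_json_round_trip(self, tube_coeffs):
        d = tube_coeffs.to_json_dict()
        back = SpharmCoeffs.from_json_dict(d)
        assert back.degree == tube_coeffs.degree
        assert np.allclose(back.coeffs, tube_coeffs.coeffs)
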
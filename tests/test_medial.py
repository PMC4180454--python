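"""Mean-latitude-axis morphometry against analytic shapes."""

import numpy as np
import pytest

from lvshape.harmonics import CorrespondedSurface
from lvshape.medial import MorphometryError, mean_latitude_axis, profiles_to_frame
from lvshape.sphere import icosphere, sphere_to_angles

from conftest import analytic_cylinder_surface


def analytic_sphere_surface(radius=10.0, subdivision=20):
    verts, faces = icosphere(subdivision)
    theta, phi = sphere_to_angles(verts)
    return CorrespondedSurface(points=verts * radius, theta=theta, phi=phi, faces=faces)


class TestCylinderOracle:
    def test_radius_length_area(self):
        surf = analytic_cylinder_surface(radius=5.0, length=40.0)
        prof = mean_latitude_axis(surf, n_bands=20)
        interior = slice(4, 16)
        assert np.allclose(prof.radius[interior], 5.0, rtol=0.05)
        assert abs(prof.total_length - 40.0) / 40.0 < 0.10
        assert np.allclose(prof.area[interior], np.pi * 25.0, rtol=0.10)

    def test_pi_r2_area_mode(self):
        surf = analytic_cylinder_surface()
        prof = mean_latitude_axis(surf, n_bands=20, area_mode="pi_r2")
        assert np.allclose(prof.area, np.pi * prof.radius**2)

    def test_anterior_first_ordering(self):
        surf = analytic_cylinder_surface()
        prof = mean_latitude_axis(surf, n_bands=20)
        # anterior tip (colatitude 0) is at +y: medial point 0 has the largest y
        assert prof.medial_points[0, 1] > prof.medial_points[-1, 1]


class TestSphereBands:
    def test_radius_profile_proportional_to_sin_colatitude(self):
        r = 10.0
        surf = analytic_sphere_surface(radius=r)
        prof = mean_latitude_axis(surf, n_bands=20)
        centers = (np.arange(20) + 0.5) * np.pi / 20
        expected = r * np.sin(centers)
        interior = slice(2, 18)
        assert np.allclose(prof.radius[interior], expected[interior], rtol=0.05)

    def test_equatorial_medial_point_near_center(self):
        r = 10.0
        surf = analytic_sphere_surface(radius=r)
        prof = mean_latitude_axis(surf, n_bands=21)
        assert np.linalg.norm(prof.medial_points[10]) < 0.05 * r


class TestInvariances:
    def test_scaling_covariance(self):
        surf = analytic_cylinder_surface()
        surf2 = CorrespondedSurface(points=surf.points * 2.0, theta=surf.theta,
                                    phi=surf.phi, faces=surf.faces)
        p1 = mean_latitude_axis(surf, n_bands=20)
        p2 = mean_latitude_axis(surf2, n_bands=20)
        assert np.allclose(p2.local_length, 2 * p1.local_length, rtol=1e-9)
        assert np.allclose(p2.radius, 2 * p1.radius, rtol=1e-9)
        assert np.allclose(p2.area, 4 * p1.area, rtol=1e-9)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        surf = analytic_cylinder_surface()
        R = Rotation.from_euler("xyz", [25, 42, -13], degrees=True).as_matrix()
        moved = CorrespondedSurface(points=surf.points @ R.T + [5, -2, 9],
                                    theta=surf.theta, phi=surf.phi, faces=surf.faces)
        p1 = mean_latitude_axis(surf, n_bands=20)
        p2 = mean_latitude_axis(moved, n_bands=20)
        assert np.allclose(p2.local_length, p1.local_length, atol=1e-9)
        assert np.allclose(p2.radius, p1.radius, atol=1e-9)
        assert np.allclose(p2.area, p1.area, atol=1e-6)

    def test_small_perturbation_small_change(self):
        rng = np.random.default_rng(0)
        surf = analytic_cylinder_surface()
        jitter = rng.standard_normal(surf.points.shape) * 0.05  # 1 % of radius
        surf2 = CorrespondedSurface(points=surf.points + jitter, theta=surf.theta,
                                    phi=surf.phi, faces=surf.faces)
        p1 = mean_latitude_axis(surf, n_bands=20)
        p2 = mean_latitude_axis(surf2, n_bands=20)
        assert np.abs(p2.radius - p1.radius).max() / 5.0 < 0.05


class TestErrors:
    def test_empty_band_message(self):
        surf = analytic_cylinder_surface(subdivision=4)  # 162 sites
        with pytest.raises(MorphometryError, match="empty colatitude band"):
            mean_latitude_axis(surf, n_bands=90)

    def test_min_bands(self):
        surf = analytic_cylinder_surface(subdivision=6)
        with pytest.raises(MorphometryError):
            mean_latitude_axis(surf, n_bands=2)

    def test_unknown_area_mode(self):
        surf = analytic_cylinder_surface(subdivision=6)
        with pytest.raises(MorphometryError):
            mean_latitude_axis(surf, n_bands=10, area_mode="banana")


def test_profiles_to_frame_tidy():
    surf = analytic_cylinder_surface(subdivision=10)
    prof = mean_latitude_axis(surf, n_bands=10)
    df = profiles_to_frame({("S1", 14.0, "F", "left"): prof})
    assert set(["subject", "age_days", "gender", "side", "band", "position",
                "length", "radius", "area"]).issubset(df.columns)
    assert len(df) == 10
    assert np.isnan(df["length"].iloc[0])  # no leading segment for band 0
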
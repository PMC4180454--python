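"""Shared fixtures: small analytic shapes and one parameterized synthetic tube.

The expensive objects (voxelized tube, its spherical parameterization and
SPHARM fit) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from lvshape.masks import LabelMask, regularize
from lvshape.meshing import SurfaceMesh, extract_surface
from lvshape.harmonics import CorrespondedSurface, fit_spharm
from lvshape.sphere import icosphere, sphere_to_angles, spherical_parameterize
from lvshape.synthetic import GrowthTruth, generate_shape


def ball_mask(radius: float = 10.0, spacing: float = 1.0) -> LabelMask:
    n = int(2 * radius / spacing) + 5
    x = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vox = X**2 + Y**2 + Z**2 <= radius**2
    aff = np.eye(4)
    aff[:3, :3] *= spacing
    aff[:3, 3] = x[0]
    return LabelMask(vox, aff)


def torus_mask(R: float = 8.0, r: float = 3.0) -> LabelMask:
    n = 2 * int(R + r) + 5
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    vox = (np.sqrt(X**2 + Y**2) - R) ** 2 + Z**2 <= r**2
    return LabelMask(vox, np.eye(4))


def analytic_cylinder_surface(
    radius: float = 5.0, length: float = 40.0, subdivision: int = 30,
    cap_frac: float = 0.08,
) -> CorrespondedSurface:
    """Closed cylinder (axis along y, anterior tip at +y) sampled at icosphere
    sites: colatitude runs tip-to-tip, caps occupy ``cap_frac`` of [0, pi] at
    each pole."""
    verts, faces = icosphere(subdivision)
    theta, phi = sphere_to_angles(verts)
    t0 = cap_frac * np.pi
    body = (theta >= t0) & (theta <= np.pi - t0)
    frac = (theta - t0) / (np.pi - 2 * t0)
    pts = np.empty((len(verts), 3))
    pts[:, 1] = np.where(
        body, length / 2 - frac * length,
        np.where(theta < t0, length / 2, -length / 2),
    )
    cap_angle = np.where(theta < t0, theta / t0, (np.pi - theta) / t0)
    rad = np.where(body, radius, radius * np.sin(np.clip(cap_angle, 0, 1) * np.pi / 2))
    pts[:, 0] = rad * np.cos(phi)
    pts[:, 2] = rad * np.sin(phi)
    return CorrespondedSurface(points=pts, theta=theta, phi=phi, faces=faces)


def analytic_ellipsoid_mesh(semi=(30.0, 20.0, 10.0), subdivision: int = 8) -> SurfaceMesh:
    v, f = icosphere(subdivision)
    return SurfaceMesh(v * np.asarray(semi), f)


@pytest.fixture(scope="session")
def tube_truth() -> GrowthTruth:
    return GrowthTruth(subject_id="T1", side="left", gender="F", noise_sd=0.15, seed=7)


@pytest.fixture(scope="session")
def tube_mask(tube_truth):
    return regularize(generate_shape(tube_truth, 182))


@pytest.fixture(scope="session")
def tube_mesh(tube_mask):
    return extract_surface(tube_mask)


@pytest.fixture(scope="session")
def tube_param(tube_mesh):
    return spherical_parameterize(tube_mesh, max_iter=600)


@pytest.fixture(scope="session")
def tube_coeffs(tube_mesh, tube_param):
    return fit_spharm(tube_mesh, tube_param, 12)


@pytest.fixture(scope="session")
def ellipsoid_mesh():
    return analytic_ellipsoid_mesh()


@pytest.fixture(scope="session")
def ellipsoid_param(ellipsoid_mesh):
    return spherical_parameterize(ellipsoid_mesh, max_iter=1500)
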
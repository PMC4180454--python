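"""Real spherical-harmonic surface descriptions (SPHARM).

Each coordinate function (x, y, z) of a spherically parameterized genus-0
surface is expanded in the real orthonormal spherical-harmonic basis up to
degree L.  The degree-1 terms describe an ellipsoid whose axes provide the
canonical frame used for correspondence alignment; sampling the series at the
vertices of a subdivided icosahedron yields the point distribution model
(PDM) with identical sample sites across all surfaces of a study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import sph_harm_y

from .meshing import SurfaceMesh
from .sphere import SphericalParam, icosphere, sphere_to_angles


class HarmonicsError(ValueError):
    """Raised for invalid harmonic fits (degenerate ellipsoid, rank issues)."""


_Y00 = 0.5 / np.sqrt(np.pi)
_C1 = np.sqrt(3.0 / (4.0 * np.pi))


def n_coeffs(degree: int) -> int:
    return (degree + 1) ** 2


def sh_index(l: int, m: int) -> int:
    """Column index of the real harmonic (l, m), m in [-l, l]."""
    return l * l + l + m


def real_sh_basis(theta: np.ndarray, phi: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal real spherical-harmonic design matrix, (npts, (L+1)^2).

    Convention: Y_{l,0} = Re Y^c_{l0}; for m > 0, Y_{l,m} = sqrt(2) (-1)^m
    Re Y^c_{lm} and Y_{l,-m} = sqrt(2) (-1)^m Im Y^c_{lm}, so that the
    degree-1 functions are proportional to the Cartesian components
    (u_y, u_z, u_x) for m = (-1, 0, +1).
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    B = np.empty((len(theta), n_coeffs(degree)))
    sqrt2 = np.sqrt(2.0)
    for l in range(degree + 1):
        for m in range(l + 1):
            Y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                B[:, sh_index(l, 0)] = Y.real
            else:
                s = sqrt2 * (-1.0) ** m
                B[:, sh_index(l, m)] = s * Y.real
                B[:, sh_index(l, -m)] = s * Y.imag
    return B


@dataclass
class SpharmCoeffs:
    """Real spherical-harmonic coefficients of the three coordinate functions."""

    degree: int
    coeffs: np.ndarray  # (3, (L+1)^2), rows x, y, z
    rms_residual: float = np.nan
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (3, n_coeffs(self.degree)):
            raise HarmonicsError(
                f"coefficient block must be (3, {n_coeffs(self.degree)}), "
                f"got {self.coeffs.shape}"
            )

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the surface over the parameter sphere (degree-0 term)."""
        return self.coeffs[:, 0] * _Y00

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        B = real_sh_basis(theta, phi, self.degree)
        return B @ self.coeffs.T

    def evaluate_basis(self, B: np.ndarray) -> np.ndarray:
        return B @ self.coeffs.T

    def to_json_dict(self) -> dict:
        return {
            "degree": self.degree,
            "coeffs": {
                c: list(map(float, self.coeffs[i]))
                for i, c in enumerate(("x", "y", "z"))
            },
            "rms_residual": float(self.rms_residual),
            "provenance": self.provenance,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SpharmCoeffs":
        coeffs = np.array([d["coeffs"][c] for c in ("x", "y", "z")])
        return cls(
            degree=int(d["degree"]),
            coeffs=coeffs,
            rms_residual=float(d.get("rms_residual", np.nan)),
            provenance=d.get("provenance", {}),
        )


def fit_spharm(
    mesh: SurfaceMesh, param: SphericalParam, degree: int, provenance: dict | None = None
) -> SpharmCoeffs:
    """Least-squares fit of the coordinate functions up to ``degree``."""
    if degree < 0:
        raise HarmonicsError(f"degree must be >= 0, got {degree}")
    if param.n_vertices != mesh.n_vertices:
        raise HarmonicsError("parameterization does not match mesh")
    K = n_coeffs(degree)
    if mesh.n_vertices < K:
        raise HarmonicsError(
            f"cannot fit {K} coefficients with only {mesh.n_vertices} vertices"
        )
    B = real_sh_basis(param.theta, param.phi, degree)
    sol, *_ = np.linalg.lstsq(B, mesh.vertices, rcond=None)
    resid = B @ sol - mesh.vertices
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return SpharmCoeffs(degree, sol.T, rms, provenance or {})


def fit_spharm_values(
    points: np.ndarray, theta: np.ndarray, phi: np.ndarray, degree: int
) -> SpharmCoeffs:
    """Fit coefficients to arbitrary (point, parameter-site) pairs."""
    B = real_sh_basis(theta, phi, degree)
    sol, *_ = np.linalg.lstsq(B, points, rcond=None)
    resid = B @ sol - points
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return SpharmCoeffs(degree, sol.T, rms)


@dataclass
class FirstOrderEllipsoid:
    """Ellipsoid implied by the degree-1 harmonic terms."""

    center: np.ndarray  # mm
    axes: np.ndarray  # (3, 3) rows: object-space unit axes, descending length
    semi_lengths: np.ndarray  # (3,) mm, descending
    param_axes: np.ndarray  # (3, 3) rows: parameter-sphere directions of the axes


def first_order_ellipsoid(
    coeffs: SpharmCoeffs, rel_rank_tol: float = 1e-6
) -> FirstOrderEllipsoid:
    """Axes and semi-lengths of the degree-1 ellipsoid.

    The degree-1 part of the series is the linear map u -> M u of the unit
    parameter sphere; its SVD gives the ellipsoid axes (left singular
    vectors), semi-lengths (singular values) and the parameter-space
    directions that map onto them (right singular vectors).
    """
    c = coeffs.coeffs
    M = np.column_stack(
        [
            _C1 * c[:, sh_index(1, 1)],  # u_x column
            _C1 * c[:, sh_index(1, -1)],  # u_y column
            _C1 * c[:, sh_index(1, 0)],  # u_z column
        ]
    )
    U, S, Vt = np.linalg.svd(M)
    if S[0] <= 0 or S[2] / S[0] < rel_rank_tol:
        raise HarmonicsError(
            "degree-1 coefficient block is rank deficient (degenerate ellipsoid)"
        )
    return FirstOrderEllipsoid(
        center=coeffs.centroid,
        axes=U.T.copy(),
        semi_lengths=S.copy(),
        param_axes=Vt.copy(),
    )


_GRID_CACHE: dict = {}


def icosphere_design(subdivision: int, degree: int):
    """Cached (theta, phi, faces, basis, pseudo-inverse) for an icosphere grid.

    The same sampling grids recur for every surface of a study; caching the
    design matrix and its pseudo-inverse makes alignment and PDM sampling
    cheap.
    """
    key = (subdivision, degree)
    if key not in _GRID_CACHE:
        verts, faces = icosphere(subdivision)
        theta, phi = sphere_to_angles(verts)
        B = real_sh_basis(theta, phi, degree)
        pinv = np.linalg.pinv(B)
        _GRID_CACHE[key] = (theta, phi, faces, B, pinv)
    return _GRID_CACHE[key]


@dataclass
class CorrespondedSurface:
    """Fixed-site sampling of a SPHARM surface (the point distribution model)."""

    points: np.ndarray  # (N, 3) mm
    theta: np.ndarray  # (N,) shared colatitude sites
    phi: np.ndarray  # (N,) shared longitude sites
    faces: np.ndarray  # (F, 3) icosphere triangulation of the sites
    provenance: dict = field(default_factory=dict)

    @property
    def n_points(self) -> int:
        return len(self.points)


def sample_pdm(coeffs: SpharmCoeffs, subdivision: int = 10) -> CorrespondedSurface:
    """Evaluate the series at a frequency-``subdivision`` icosahedral grid.

    Yields N = 10 n^2 + 2 corresponded points; every surface sampled with the
    same ``subdivision`` shares sample sites point-for-point.
    """
    if subdivision < 1:
        raise HarmonicsError(f"subdivision must be >= 1, got {subdivision}")
    theta, phi, faces, B, _ = icosphere_design(subdivision, coeffs.degree)
    pts = coeffs.evaluate_basis(B)
    return CorrespondedSurface(
        points=pts, theta=theta, phi=phi, faces=faces,
        provenance=dict(coeffs.provenance),
    )
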
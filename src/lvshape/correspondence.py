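"""Correspondence alignment of SPHARM surfaces and its landmark validation.

Correspondence across surfaces is established in two steps:

1. *Parameter alignment*: each surface's parameter sphere is rotated so the
   parameter directions of its first-order ellipsoid axes land on canonical
   sphere axes — the long axis at the poles (north = anterior end), the
   second axis at the phi = 0 meridian.  Points mapping to the same
   parameter-space position are then anatomically corresponding.
2. *Object alignment*: rigid Procrustes (rotation + translation, no scaling
   — the analysis studies growth, so scale is signal) of each surface's
   sampled point set onto the first surface in the list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .harmonics import (
    CorrespondedSurface,
    HarmonicsError,
    SpharmCoeffs,
    first_order_ellipsoid,
    fit_spharm_values,
    sample_pdm,
)
from .sphere import icosphere, sphere_to_angles

_TWO_SQRT_PI = 2.0 * np.sqrt(np.pi)

#: Default anatomical axis hints (RAS): anterior = +y, superior = +z.
ANTERIOR_AXIS = np.array([0.0, 1.0, 0.0])
SUPERIOR_AXIS = np.array([0.0, 0.0, 1.0])


class AlignmentError(ValueError):
    """Raised for ambiguous or impossible alignments."""


def _fix_axis_signs(ell, anterior_axis, superior_axis):
    """Resolve the 4-fold axis flip ambiguity with anatomical direction hints."""
    axes = ell.axes.copy()
    pax = ell.param_axes.copy()
    if float(axes[0] @ anterior_axis) < 0:
        axes[0], pax[0] = -axes[0], -pax[0]
    if float(axes[1] @ superior_axis) < 0:
        axes[1], pax[1] = -axes[1], -pax[1]
    # make the frame right-handed; flip the pair to keep M = sum s_i u_i v_i^T
    cross = np.cross(axes[0], axes[1])
    if float(cross @ axes[2]) < 0:
        axes[2], pax[2] = -axes[2], -pax[2]
    return axes, pax


def rotate_parameterization(
    coeffs: SpharmCoeffs, r_param: np.ndarray, fit_subdivision: int = 16
) -> SpharmCoeffs:
    """Rotate the parameter sphere by ``r_param`` and refit the coefficients.

    A rotation of the parameter domain maps the degree-<=L space onto
    itself, so refitting on a dense spherical grid is exact up to numerics.
    """
    from .harmonics import icosphere_design
    from .sphere import angles_to_sphere

    theta_g, phi_g, _, _, pinv = icosphere_design(fit_subdivision, coeffs.degree)
    grid = angles_to_sphere(theta_g, phi_g)
    theta_s, phi_s = sphere_to_angles(grid @ r_param)  # R^T applied to grid
    pts = coeffs.evaluate(theta_s, phi_s)
    sol = pinv @ pts
    return SpharmCoeffs(coeffs.degree, sol.T, coeffs.rms_residual, dict(coeffs.provenance))


def apply_rigid(coeffs: SpharmCoeffs, rotation: np.ndarray, translation) -> SpharmCoeffs:
    """Apply an object-space rigid motion directly in coefficient space."""
    c = rotation @ coeffs.coeffs
    c[:, 0] += np.asarray(translation, dtype=float) * _TWO_SQRT_PI
    return SpharmCoeffs(coeffs.degree, c, coeffs.rms_residual, dict(coeffs.provenance))


def kabsch(moving: np.ndarray, reference: np.ndarray):
    """Rigid Procrustes: rotation + translation mapping moving -> reference."""
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (moving - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_r - R @ mu_m
    return R, t


def align(
    coeffs_list: Sequence[SpharmCoeffs],
    anterior_axis=ANTERIOR_AXIS,
    superior_axis=SUPERIOR_AXIS,
    axis_tol: float = 0.02,
    sample_subdivision: int = 10,
):
    """Align a study's SPHARM surfaces in parameter and object space.

    Returns the aligned coefficient list.  Surfaces whose first-order
    ellipsoid has two semi-lengths equal within ``axis_tol`` (relative) are
    rejected: the canonical frame would be arbitrary, silently corrupting
    correspondence.
    """
    if len(coeffs_list) < 2:
        raise AlignmentError("alignment needs at least two surfaces")
    degrees = {c.degree for c in coeffs_list}
    if len(degrees) != 1:
        raise AlignmentError(f"mixed harmonic degrees {sorted(degrees)}")
    anterior_axis = np.asarray(anterior_axis, dtype=float)
    superior_axis = np.asarray(superior_axis, dtype=float)

    rotated = []
    for i, coeffs in enumerate(coeffs_list):
        ell = first_order_ellipsoid(coeffs)
        s = ell.semi_lengths
        if (s[0] - s[1]) / s[0] < axis_tol or (s[1] - s[2]) / s[0] < axis_tol:
            raise AlignmentError(
                f"surface {i}: ellipsoid semi-lengths {np.round(s, 3)} are ambiguous "
                f"(two axes equal within {axis_tol:.0%}); supply a manual axis hint"
            )
        _, pax = _fix_axis_signs(ell, anterior_axis, superior_axis)
        # rows of r_param send (v2, v3, v1) -> (e_x, e_y, e_z): long axis to poles
        r_param = np.vstack([pax[1], pax[2], pax[0]])
        rotated.append(rotate_parameterization(coeffs, r_param))

    reference = sample_pdm(rotated[0], sample_subdivision).points
    aligned = [rotated[0]]
    for coeffs in rotated[1:]:
        pts = sample_pdm(coeffs, sample_subdivision).points
        R, t = kabsch(pts, reference)
        aligned.append(apply_rigid(coeffs, R, t))
    return aligned


def landmark_correspondence_error(
    template: CorrespondedSurface,
    targets: Sequence[CorrespondedSurface],
    landmarks: Sequence,
    manual_positions: np.ndarray,
):
    """Distances between manual landmark positions and corresponded points.

    ``landmarks`` are point indices on the template (mm positions are snapped
    to the nearest template point).  ``manual_positions`` has shape
    (n_targets, n_landmarks, 3): the manually located positions of each
    landmark on each target.  Returns a tidy DataFrame with per-landmark and
    per-target mean +/- sd summaries attached as attrs.
    """
    import pandas as pd

    idx = []
    for lm in landmarks:
        if np.ndim(lm) == 0:
            k = int(lm)
            if not 0 <= k < template.n_points:
                raise AlignmentError(f"landmark index {k} out of range")
        else:
            k = int(np.linalg.norm(template.points - np.asarray(lm), axis=1).argmin())
        idx.append(k)
    manual = np.asarray(manual_positions, dtype=float)
    if manual.shape != (len(targets), len(idx), 3):
        raise AlignmentError(
            f"manual positions must be (n_targets, n_landmarks, 3), got {manual.shape}"
        )
    rows = []
    for ti, target in enumerate(targets):
        corresponded = target.points[idx]
        d = np.linalg.norm(corresponded - manual[ti], axis=1)
        for li, dist in enumerate(d):
            rows.append(
                dict(target=ti, landmark=li, point_index=idx[li], distance_mm=dist)
            )
    table = pd.DataFrame(rows)
    table.attrs["per_landmark"] = table.groupby("landmark")["distance_mm"].agg(
        ["mean", "std"]
    )
    table.attrs["per_target"] = table.groupby("target")["distance_mm"].agg(
        ["mean", "std"]
    )
    return table
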
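"""Per-vertex principal growth directions by SVD of displacement vectors.

For every corresponded vertex the displacement vectors d = x(later visit) -
x(first visit), stacked over all subjects and later visits, form an m x 3
matrix.  Its singular value decomposition — *without* column centering,
because the mean displacement is the growth signal — yields the principal
growth direction (first right singular vector, sign chosen so the mean
projection of the displacements onto it is nonnegative) and the growth rate
(mean projection per month along that direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sphere import icosphere


class GrowthError(ValueError):
    """Raised for invalid growth-field inputs."""


#: Days per month used for growth rates.
DAYS_PER_MONTH = 30.4375


@dataclass
class GrowthField:
    """Per-vertex growth direction, singular-value spectrum, and rate."""

    principal_direction: np.ndarray  # (V, 3) unit vectors
    singular_values: np.ndarray  # (V, 3) descending, mm
    growth_rate: np.ndarray  # (V,) mm per month along principal_direction
    n_vectors: int  # displacement vectors per vertex
    axes: np.ndarray  # (V, 3, 3) right singular vectors (rows)

    @property
    def n_points(self) -> int:
        return len(self.principal_direction)


def growth_directions(
    W: np.ndarray,
    covariates: pd.DataFrame,
    reference: str = "first",
) -> GrowthField:
    """Estimate the growth field from aligned corresponded coordinates.

    ``W`` is (n_obs, V, 3) with one row per subject/visit; ``covariates``
    needs ``subject`` and ``age_days``.  ``reference="first"`` differences
    every later visit against the subject's first visit (the default);
    ``reference="consecutive"`` uses adjacent-visit differences instead.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 3 or W.shape[2] != 3:
        raise GrowthError(f"W must be (n_obs, V, 3), got {W.shape}")
    if reference not in ("first", "consecutive"):
        raise GrowthError(f"unknown reference mode {reference!r}")
    subj = covariates["subject"].to_numpy()
    ages = covariates["age_days"].to_numpy(dtype=float)

    diffs = []  # (V, 3) arrays
    dts = []  # months
    for s in pd.unique(subj):
        sel = np.flatnonzero(subj == s)
        sel = sel[np.argsort(ages[sel], kind="stable")]
        if len(sel) < 2:
            continue
        if reference == "first":
            base, laters = sel[0], sel[1:]
            for j in laters:
                diffs.append(W[j] - W[base])
                dts.append((ages[j] - ages[base]) / DAYS_PER_MONTH)
        else:
            for a, b in zip(sel[:-1], sel[1:]):
                diffs.append(W[b] - W[a])
                dts.append((ages[b] - ages[a]) / DAYS_PER_MONTH)
    m = len(diffs)
    if m == 0:
        raise GrowthError("no subject has two or more visits; growth undefined")
    D = np.stack(diffs, axis=1)  # (V, m, 3)
    dts = np.asarray(dts)

    # batched SVD, no centering
    _, S, Vt = np.linalg.svd(D, full_matrices=False)
    Vt = Vt.copy()
    direction = Vt[:, 0, :].copy()
    proj = np.einsum("vmj,vj->vm", D, direction)  # (V, m)
    flip = proj.mean(axis=1) < 0
    direction[flip] *= -1.0
    Vt[flip, 0, :] = direction[flip]
    proj[flip] *= -1.0
    rate = (proj / dts[None, :]).mean(axis=1)
    return GrowthField(
        principal_direction=direction,
        singular_values=S,
        growth_rate=rate,
        n_vectors=m,
        axes=Vt,
    )


def render_growth_ellipsoids(
    field: GrowthField,
    surface_points: np.ndarray,
    subsample: int = 1,
    scale: float = 1.0,
):
    """Ellipsoid glyphs visualizing the growth field.

    Glyph axes are proportional to the singular values (normalized by the
    largest over the field, times ``scale`` mm) and oriented along the right
    singular vectors; the glyph scalar is the growth rate.  Returns
    ``(vertices, faces, rates)`` of one combined triangle soup, suitable for
    :func:`lvshape.vtkio.write_vtk_polydata`.
    """
    surface_points = np.asarray(surface_points, dtype=float)
    if len(surface_points) != field.n_points:
        raise GrowthError("surface points do not match the growth field")
    base_v, base_f = icosphere(2)
    smax = float(field.singular_values.max())
    norm = smax if smax > 0 else 1.0
    verts, faces, rates = [], [], []
    offset = 0
    idx = np.arange(field.n_points)[::subsample]
    for i in idx:
        radii = field.singular_values[i] / norm * scale
        A = field.axes[i].T * radii[None, :]  # columns scaled axes
        v = base_v @ A.T + surface_points[i]
        verts.append(v)
        faces.append(base_f + offset)
        rates.append(np.full(len(base_v), field.growth_rate[i]))
        offset += len(base_v)
    return (
        np.concatenate(verts),
        np.concatenate(faces),
        np.concatenate(rates),
    )
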
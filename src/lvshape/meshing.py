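"""Voxel-boundary (cuberille) surface extraction.

The boundary of a well-composed voxel set is a closed 2-manifold made of unit
squares between foreground voxels and their 6-neighbour background voxels.
Each square is split into two triangles with consistent outward orientation.
The enclosed mesh volume equals voxel count x voxel volume exactly, so the
mesh is a faithful geometric stand-in for the segmentation itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .masks import LabelMask, MaskError


class MeshError(ValueError):
    """Raised for invalid surface meshes (open, non-manifold, wrong genus)."""


@dataclass
class SurfaceMesh:
    """Closed triangulated surface in mm coordinates, outward-oriented faces."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray  # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def genus(self) -> int:
        chi = self.euler_characteristic()
        if chi % 2 != 0:
            raise MeshError(f"odd Euler characteristic {chi}: surface is not closed")
        return (2 - chi) // 2

    def face_normals_areas(self):
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        a = 0.5 * np.linalg.norm(n, axis=1)
        return n, a

    def face_areas(self) -> np.ndarray:
        return self.face_normals_areas()[1]

    def area(self) -> float:
        return float(self.face_areas().sum())

    def enclosed_volume(self) -> float:
        """Signed volume via the divergence theorem (positive if outward)."""
        v = self.vertices
        f = self.faces
        return float(
            np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum()
            / 6.0
        )

    def vertex_adjacency(self):
        """Sparse symmetric vertex adjacency matrix."""
        from scipy import sparse

        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e))
        adj = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        adj = adj + adj.T
        return adj.tocsr()

    def validate_closed_manifold(self) -> None:
        """Check each directed edge appears exactly once (closed, consistent)."""
        de = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        key = de[:, 0] * (self.n_vertices + 1) + de[:, 1]
        uniq, counts = np.unique(key, return_counts=True)
        if (counts > 1).any():
            raise MeshError("non-manifold or inconsistently oriented surface")
        rkey = de[:, 1] * (self.n_vertices + 1) + de[:, 0]
        if not np.isin(rkey, uniq).all():
            raise MeshError("surface has boundary edges (not closed)")
        _, areas = self.face_normals_areas()
        if (areas <= 0).any():
            raise MeshError("surface contains degenerate (zero-area) faces")


# Quad corner offsets (in corner-grid units) for a face of a voxel at (i,j,k),
# keyed by (axis, direction).  Corners are ordered counter-clockwise when
# viewed from outside the voxel.
_FACE_CORNERS = {
    (0, +1): [(1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)],
    (0, -1): [(0, 0, 0), (0, 0, 1), (0, 1, 1), (0, 1, 0)],
    (1, +1): [(0, 1, 0), (0, 1, 1), (1, 1, 1), (1, 1, 0)],
    (1, -1): [(0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)],
    (2, +1): [(0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
    (2, -1): [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 0, 0)],
}


def extract_surface(mask: LabelMask, check_genus: bool = True) -> SurfaceMesh:
    """Extract the closed voxel-boundary surface of a regularized mask.

    Vertices sit on voxel corners in physical mm; faces are outward-oriented.
    Raises :class:`MeshError` if ``check_genus`` and the surface is not
    genus 0 (required by spherical parameterization).
    """
    v = mask.voxels
    if not v.any():
        raise MaskError("empty mask")
    pad = np.pad(v, 1)
    shape_c = np.asarray(v.shape) + 1  # corner grid
    quads = []
    for axis in range(3):
        for direction in (+1, -1):
            nb = np.roll(pad, -direction, axis=axis)[1:-1, 1:-1, 1:-1]
            idx = np.argwhere(v & ~nb)  # boundary voxels for this face type
            if len(idx) == 0:
                continue
            corners = np.asarray(_FACE_CORNERS[(axis, direction)])
            quad = idx[:, None, :] + corners[None, :, :]  # (q, 4, 3)
            quads.append(quad)
    if not quads:
        raise MaskError("mask has no boundary faces")
    quads = np.concatenate(quads)  # (Q, 4, 3) corner-grid indices
    flat = (
        quads[..., 0] * (shape_c[1] * shape_c[2])
        + quads[..., 1] * shape_c[2]
        + quads[..., 2]
    )
    uniq, inv = np.unique(flat, return_inverse=True)
    quad_ids = inv.reshape(flat.shape)
    corner_ijk = np.stack(np.unravel_index(uniq, shape_c), axis=1).astype(float)
    # corner (i,j,k) is at voxel-index coordinates (i-1/2, j-1/2, k-1/2)
    verts = (mask.affine[:3, :3] @ (corner_ijk - 0.5).T).T + mask.affine[:3, 3]
    faces = np.concatenate([quad_ids[:, [0, 1, 2]], quad_ids[:, [0, 2, 3]]])
    mesh = SurfaceMesh(verts, faces)
    if mesh.enclosed_volume() < 0:  # left-handed affine: flip orientation
        mesh = SurfaceMesh(verts, faces[:, ::-1])
    mesh.validate_closed_manifold()
    if check_genus:
        g = mesh.genus()
        if g != 0:
            raise MeshError(
                f"surface has genus {g} (Euler characteristic "
                f"{mesh.euler_characteristic()}), expected genus 0"
            )
    return mesh


def genus_of_mask(mask: LabelMask) -> int:
    """Genus of the voxel-boundary surface (after well-composed extraction)."""
    mesh = extract_surface(mask, check_genus=False)
    return mesh.genus()


def mirror_sagittal(mask: LabelMask) -> LabelMask:
    """Mirror a mask across the mid-sagittal plane (x -> -x in mm).

    Implemented by flipping the voxel array along the dominant x axis and
    negating the corresponding affine column, so voxel contents are preserved
    bit-for-bit.
    """
    ax = int(np.argmax(np.abs(mask.affine[0, :3])))
    vox = np.flip(mask.voxels, axis=ax).copy()
    aff = mask.affine.copy()
    # position of flipped voxel j is position of original (n-1-j)
    n = mask.voxels.shape[ax]
    aff[:3, 3] = aff[:3, 3] + aff[:3, ax] * (n - 1)
    aff[:3, ax] = -aff[:3, ax]
    aff[0, :3] = -aff[0, :3]
    aff[0, 3] = -aff[0, 3]
    return LabelMask(vox, aff)
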
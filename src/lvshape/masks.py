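"""Binary label-mask handling: I/O, regularization, resampling, overlap.

All geometry downstream works in physical millimetres with an RAS axis
convention (+x right, +y anterior, +z superior).  Voxel indices are 0-based;
the affine maps voxel index -> mm.  Masks are regularized so that the
foreground is a single 6-connected component without interior cavities and is
*well-composed*, which guarantees that the voxel-boundary surface extracted by
:mod:`lvshape.meshing` is a closed 2-manifold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


class MaskError(ValueError):
    """Raised for invalid or degenerate mask inputs."""


#: 6-connectivity structuring element for the foreground.
STRUCT_6 = ndimage.generate_binary_structure(3, 1)
#: 26-connectivity structuring element for the background complement.
STRUCT_26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class LabelMask:
    """A 3-D binary volume with voxel geometry.

    Parameters
    ----------
    voxels
        Boolean foreground array.
    affine
        4x4 voxel-index -> mm affine (RAS).
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.voxels.ndim != 3:
            raise MaskError(f"mask must be 3-D, got shape {self.voxels.shape}")
        if self.affine.shape != (4, 4):
            raise MaskError("affine must be 4x4")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def volume_mm3(self) -> float:
        """Foreground volume = voxel count x voxel volume."""
        return float(self.voxels.sum()) * self.voxel_volume

    def orientation(self) -> str:
        return "".join(nib.aff2axcodes(self.affine))

    def copy(self) -> "LabelMask":
        return LabelMask(self.voxels.copy(), self.affine.copy())


def load_mask(path) -> LabelMask:
    """Load a NIfTI volume and binarize it (any nonzero voxel -> foreground)."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # pragma: no cover - nibabel error paths
        raise MaskError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise MaskError(f"{path!r} is not a 3-D volume (shape {data.shape})")
    vox = data != 0
    if not vox.any():
        raise MaskError(f"empty mask: {path!r} contains no nonzero voxel")
    return LabelMask(vox, np.asarray(img.affine, dtype=float))


def save_mask(mask: LabelMask, path) -> None:
    """Write a mask as uint8 NIfTI with its affine (RAS orientation recorded)."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Well-composedness repair
# ---------------------------------------------------------------------------

_DIAGONAL_PAIRS = ((0, 7), (1, 6), (2, 5), (3, 4))  # opposite corners of a 2x2x2 block


def _corner_views(v: np.ndarray) -> list:
    """The 8 corner sub-array *views* of every 2x2x2 block, by binary index."""
    return [
        v[i : v.shape[0] - 1 + i, j : v.shape[1] - 1 + j, k : v.shape[2] - 1 + k]
        for i in (0, 1)
        for j in (0, 1)
        for k in (0, 1)
    ]


def _repair_plane_diagonals(v: np.ndarray) -> int:
    """Fill voxels breaking 2x2 checkerboard (edge-critical) configurations."""
    n_fixed = 0
    for ax_a, ax_b in ((0, 1), (0, 2), (1, 2)):
        sl = [slice(None)] * 3

        def block(da, db):
            s = list(sl)
            s[ax_a] = slice(da, v.shape[ax_a] - 1 + da)
            s[ax_b] = slice(db, v.shape[ax_b] - 1 + db)
            return tuple(s)

        v00, v01 = v[block(0, 0)], v[block(0, 1)]
        v10, v11 = v[block(1, 0)], v[block(1, 1)]
        crit_main = v00 & v11 & ~v01 & ~v10
        crit_anti = ~v00 & ~v11 & v01 & v10
        n_fixed += int(crit_main.sum() + crit_anti.sum())
        v01[crit_main] = True
        v00[crit_anti] = True
    return n_fixed


def _repair_corner_diagonals(v: np.ndarray) -> int:
    """Fill voxels breaking 2x2x2 corner-critical configurations."""
    c = _corner_views(v)
    n_fixed = 0
    for a, b in _DIAGONAL_PAIRS:
        count = np.sum([x.astype(np.int8) for x in c], axis=0)
        crit_fg = (count == 2) & c[a] & c[b]
        # fill a face-neighbour of corner `a` (binary index differing in one bit)
        c[a ^ 1][crit_fg] = True
        crit_bg = (count == 6) & ~c[a] & ~c[b]
        c[a][crit_bg] = True
        n_fixed += int(crit_fg.sum() + crit_bg.sum())
    return n_fixed


def make_well_composed(voxels: np.ndarray, max_passes: int = 200) -> np.ndarray:
    """Minimally dilate a binary volume until it is well-composed.

    A well-composed set has no 2x2 checkerboard in any axis plane and no
    corner-opposite voxel pair in any 2x2x2 block (in foreground or
    background), which guarantees its voxel boundary is a 2-manifold.
    Repairs are monotone fills, so the loop terminates.
    """
    v = np.asarray(voxels).astype(bool).copy()
    for _ in range(max_passes):
        fixed = _repair_plane_diagonals(v)
        fixed += _repair_corner_diagonals(v)
        if fixed == 0:
            return v
    raise MaskError("well-composedness repair did not converge")


# ---------------------------------------------------------------------------
# Regularization
# ---------------------------------------------------------------------------


def _largest_component(v: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(v, structure=STRUCT_6)
    if n == 0:
        raise MaskError("empty mask")
    if n == 1:
        return v
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def _fill_cavities(v: np.ndarray) -> np.ndarray:
    """Fill background components (26-connected) not touching the border."""
    bg = ~v
    labels, n = ndimage.label(bg, structure=STRUCT_26)
    border = np.unique(
        np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
    )
    keep = np.isin(labels, border[border > 0])
    return ~keep if n > 0 else v


def regularize(mask: LabelMask, smooth_if_needed: bool = True) -> LabelMask:
    """Regularize a mask for spherical parameterization.

    Keeps the largest 6-connected component, fills interior cavities, and
    repairs well-composedness.  If the resulting boundary surface is not genus
    0, one minimal morphological closing-then-opening with a 6-connected
    1-voxel element is applied and the steps repeated.  Idempotent.
    """
    from .meshing import extract_surface, genus_of_mask  # local import, cycle

    v = _largest_component(mask.voxels)
    v = _fill_cavities(v)
    v = make_well_composed(v)
    v = _fill_cavities(v)  # repair fills can close off new cavities
    out = LabelMask(v, mask.affine)
    g = genus_of_mask(out)
    if g != 0 and smooth_if_needed:
        pad = np.pad(v, 2)
        pad = ndimage.binary_closing(pad, structure=STRUCT_6)
        pad = ndimage.binary_opening(pad, structure=STRUCT_6)
        v = pad[2:-2, 2:-2, 2:-2]
        v = _largest_component(v)
        v = _fill_cavities(v)
        v = make_well_composed(v)
        v = _fill_cavities(v)
        out = LabelMask(v, mask.affine)
        g = genus_of_mask(out)
    if g != 0:
        mesh = extract_surface(out, check_genus=False)
        raise MaskError(
            f"mask surface has genus {g} (Euler characteristic "
            f"{mesh.euler_characteristic()}); cannot be spherically parameterized"
        )
    return out


def resample_isotropic(mask: LabelMask, target_spacing: float = 1.0) -> LabelMask:
    """Nearest-neighbour resample onto an isotropic grid of ``target_spacing`` mm."""
    if target_spacing <= 0:
        raise MaskError(f"target_spacing must be > 0, got {target_spacing}")
    spacing = mask.spacing
    if np.allclose(spacing, target_spacing):
        return mask.copy()
    factors = spacing / target_spacing
    out = ndimage.zoom(mask.voxels.astype(np.uint8), factors, order=0) > 0
    new_affine = mask.affine.copy()
    new_affine[:3, :3] = mask.affine[:3, :3] / factors[np.newaxis, :]
    return LabelMask(out, new_affine)


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two masks on the same grid."""
    if a.voxels.shape != b.voxels.shape:
        raise MaskError(
            f"masks live on different grids: {a.voxels.shape} vs {b.voxels.shape}"
        )
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise MaskError("masks live on different grids (affines differ)")
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na + nb == 0:
        raise MaskError("both masks are empty; Dice undefined")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)
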
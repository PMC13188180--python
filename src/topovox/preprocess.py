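"""Volume I/O, isotropic resampling, ROI intensity normalization and mask utilities.

The unit of imaging input is a :class:`VoxelGrid`: a 2D/3D scalar intensity
array with physical voxel spacing, an origin, and an optional binary region
of interest (ROI) mask of the same shape.  Downstream topological analysis
operates on intensities normalized to the 0-255 filtration scale inside the
ROI; everything outside the ROI is left untouched here and excluded later by
the filtration builder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


class DegenerateROIError(ValueError):
    """Raised when an operation requires a non-empty ROI mask."""


@dataclass
class VoxelGrid:
    """A scalar image volume with spacing, origin and optional binary ROI mask.

    Parameters
    ----------
    data : ndarray
        2D or 3D intensity array. Arbitrary units on input; values inside the
        mask lie in [0, 255] after :func:`normalize_roi`.
    spacing : tuple of float
        Voxel edge lengths in mm, one per axis; all positive.
    origin : tuple of float
        Physical coordinate of the first voxel, in mm.
    mask : ndarray or None
        Binary ROI array with the same shape as ``data``.
    """

    data: np.ndarray
    spacing: tuple = None
    origin: tuple = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D volume, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != self.data.ndim or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing} for ndim={self.data.ndim}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} != data shape {self.data.shape}"
                )
            self.mask = self.mask.astype(bool)

    @property
    def shape(self):
        return self.data.shape

    def require_mask(self) -> np.ndarray:
        if self.mask is None:
            raise DegenerateROIError("operation requires an ROI mask")
        if not self.mask.any():
            raise DegenerateROIError("ROI mask is empty")
        return self.mask


def _affine_from(spacing, origin):
    aff = np.eye(4)
    sp = list(spacing) + [1.0] * (3 - len(spacing))
    org = list(origin) + [0.0] * (3 - len(origin))
    aff[:3, :3] = np.diag(sp)
    aff[:3, 3] = org
    return aff


def load_volume(path, mask_path=None) -> VoxelGrid:
    """Read a NIfTI volume (and optionally a companion ROI mask) from disk.

    Spacing and origin are taken from the header; intensities are returned
    unmodified.  Raises a shape error for non-3D images and lets nibabel's
    I/O errors propagate for unreadable files.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asanyarray(mimg.dataobj)
        if mask.shape != data.shape:
            raise ValueError("mask shape does not match volume shape")
        mask = mask > 0
    return VoxelGrid(data=data, spacing=spacing, origin=origin, mask=mask)


def save_volume(grid: VoxelGrid, path, mask_path=None) -> None:
    """Write a VoxelGrid (and optionally its mask) as NIfTI."""
    aff = _affine_from(grid.spacing, grid.origin)
    nib.save(nib.Nifti1Image(np.asarray(grid.data, dtype=np.float32), aff), str(path))
    if mask_path is not None and grid.mask is not None:
        nib.save(nib.Nifti1Image(grid.mask.astype(np.uint8), aff), str(mask_path))


def _resample_array(arr, in_spacing, target_mm, order):
    in_shape = arr.shape
    out_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(in_shape, in_spacing)
    )
    coords = np.meshgrid(
        *[np.arange(m) * (target_mm / s) for m, s in zip(out_shape, in_spacing)],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(arr, dtype=float), np.stack(coords), order=order, mode="nearest"
    )
    return out, out_shape


def resample_isotropic(grid: VoxelGrid, target_mm: float = 1.0, is_mask: bool = False) -> VoxelGrid:
    """Resample to an isotropic grid of edge length ``target_mm``.

    Intensities are linearly interpolated; masks (the companion ``grid.mask``
    and, when ``is_mask`` is set, ``data`` itself) use nearest-neighbor
    interpolation so labels stay binary.  Output shape per axis is
    ``round(n * spacing / target_mm)``.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if all(abs(s - target_mm) < 1e-12 for s in grid.spacing):
        return replace(
            grid,
            data=grid.data.copy(),
            mask=None if grid.mask is None else grid.mask.copy(),
        )
    order = 0 if is_mask else 1
    data, _ = _resample_array(grid.data, grid.spacing, target_mm, order=order)
    if is_mask:
        data = (data > 0.5).astype(grid.data.dtype)
    mask = None
    if grid.mask is not None:
        m, _ = _resample_array(grid.mask.astype(np.uint8), grid.spacing, target_mm, order=0)
        mask = m > 0.5
    return VoxelGrid(
        data=data,
        spacing=(target_mm,) * grid.data.ndim,
        origin=grid.origin,
        mask=mask,
    )


def normalize_roi(grid: VoxelGrid) -> VoxelGrid:
    """Min-max normalize in-mask intensities to [0, 255].

    Uses the in-mask minimum and maximum; voxels outside the mask are left
    untouched.  A constant-intensity ROI maps to all zeros so the downstream
    filtration stays defined.
    """
    mask = grid.require_mask()
    data = np.asarray(grid.data, dtype=float).copy()
    vals = data[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        data[mask] = 0.0
    else:
        data[mask] = 255.0 * (vals - lo) / (hi - lo)
    return replace(grid, data=data, mask=grid.mask.copy())


def crop_to_roi(grid: VoxelGrid, pad: int = 0) -> VoxelGrid:
    """Restrict the grid to the mask's bounding box expanded by ``pad`` voxels."""
    mask = grid.require_mask()
    if pad < 0:
        raise ValueError("pad must be nonnegative")
    idx = np.nonzero(mask)
    sl = tuple(
        slice(max(0, int(i.min()) - pad), min(n, int(i.max()) + 1 + pad))
        for i, n in zip(idx, mask.shape)
    )
    origin = tuple(
        o + s.start * sp for o, s, sp in zip(grid.origin, sl, grid.spacing)
    )
    return VoxelGrid(
        data=grid.data[sl].copy(),
        spacing=grid.spacing,
        origin=origin,
        mask=mask[sl].copy(),
    )


def dice_coefficient(mask_a, mask_b) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) between two binary masks.

    Both-empty masks return 1.0 (the conventional limit of perfect agreement).
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
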
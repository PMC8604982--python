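"""Synthetic parcellation atlas: contiguous cubic parcels in a NIfTI volume."""

from __future__ import annotations

import numpy as np

__all__ = ["gen_atlas", "parcel_centers"]


def gen_atlas(
    grid_shape=(4, 4, 4),
    parcel_size_mm: float = 16.0,
    voxel_size_mm: float = 2.0,
    affine: np.ndarray | None = None,
    pad_parcels: int = 1,
):
    """Generate an integer label volume of cubic parcels.

    ``grid_shape`` counts parcels per axis; each parcel is a cube of
    ``parcel_size_mm`` per side built from isotropic voxels of
    ``voxel_size_mm`` (the parcel size must be a multiple of the voxel size).
    Labels run 1..K in raster order; a border of ``pad_parcels`` parcel widths
    of background (label 0) surrounds the grid. The default affine is RAS+
    with the volume centered on the origin, so parcels span negative and
    positive mm coordinates like an MNI bounding box.

    Returns a ``nibabel.Nifti1Image`` with int32 data.
    """
    import nibabel as nib

    grid = np.asarray(grid_shape, dtype=int)
    if grid.shape != (3,) or np.any(grid <= 0):
        raise ValueError("grid_shape must be three positive parcel counts")
    if parcel_size_mm <= 0 or voxel_size_mm <= 0:
        raise ValueError("parcel and voxel sizes must be positive")
    vox_per_parcel = parcel_size_mm / voxel_size_mm
    if abs(vox_per_parcel - round(vox_per_parcel)) > 1e-9:
        raise ValueError("parcel_size_mm must be a multiple of voxel_size_mm")
    vpp = int(round(vox_per_parcel))
    if pad_parcels < 0:
        raise ValueError("pad_parcels must be non-negative")

    shape = (grid + 2 * pad_parcels) * vpp
    data = np.zeros(shape, dtype=np.int32)
    label = 0
    for i in range(grid[0]):
        for j in range(grid[1]):
            for k in range(grid[2]):
                label += 1
                i0 = (i + pad_parcels) * vpp
                j0 = (j + pad_parcels) * vpp
                k0 = (k + pad_parcels) * vpp
                data[i0 : i0 + vpp, j0 : j0 + vpp, k0 : k0 + vpp] = label

    if affine is None:
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        # Center the volume: voxel (shape-1)/2 maps to the mm origin.
        affine[:3, 3] = -voxel_size_mm * (shape - 1) / 2.0
    return nib.Nifti1Image(data, np.asarray(affine, dtype=float))


def parcel_centers(img) -> dict:
    """Map each nonzero label to the mm coordinate of its voxel centroid."""
    data = np.asarray(img.dataobj).astype(int)
    affine = np.asarray(img.affine, dtype=float)
    centers = {}
    for label in np.unique(data):
        if label == 0:
            continue
        ijk = np.argwhere(data == label).mean(axis=0)
        centers[int(label)] = tuple((affine @ np.append(ijk, 1.0))[:3])
    return centers
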
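"""Volume I/O in NIfTI with the package's grid conventions.

Scalar fields are written as (nx, ny, 1) volumes, vector fields as
(nx, ny, 1, ncomp), and symmetric tensors as 6-component volumes in
lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz) — the order is recorded
in the header description.  Affines are in mm with the voxel-centered
convention (voxel (0,0) center at origin + spacing/2); reading checks the
affine against the target grid and fails loudly on mismatch.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .grids import VoxelGrid

TENSOR_ORDER_NOTE = "tensor order: xx,xy,yy,xz,yz,zz"


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = grid.spacing[0]
    aff[1, 1] = grid.spacing[1]
    aff[2, 2] = grid.thickness_mm
    aff[0, 3] = grid.origin[0] + 0.5 * grid.spacing[0]
    aff[1, 3] = grid.origin[1] + 0.5 * grid.spacing[1]
    return aff


def write_volume(path, array: np.ndarray, grid: VoxelGrid,
                 description: str = "") -> None:
    """Write a scalar/vector/tensor field as a 64-bit NIfTI volume."""
    a = np.asarray(array, dtype=np.float64)
    if a.shape[:2] != grid.shape:
        raise ValueError("array shape does not match grid")
    if a.ndim == 2:
        a = a[:, :, None]
    elif a.ndim == 3:                       # (nx, ny, ncomp) -> add z axis
        a = a[:, :, None, :]
    img = nib.Nifti1Image(a, _affine(grid))
    if a.ndim == 4 and a.shape[-1] == 6 and not description:
        description = TENSOR_ORDER_NOTE
    img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def read_volume(path, grid: VoxelGrid = None) -> np.ndarray:
    """Read a volume; if ``grid`` is given, verify shape and affine."""
    img = nib.load(str(path))
    a = np.asarray(img.dataobj, dtype=np.float64)
    if grid is not None:
        if a.shape[:2] != grid.shape:
            raise ValueError(
                f"volume shape {a.shape[:2]} does not match grid {grid.shape}")
        if not np.allclose(img.affine, _affine(grid), atol=1e-6):
            raise ValueError("volume affine inconsistent with grid "
                             "(spacing/origin mismatch)")
    if a.ndim == 3 and a.shape[2] == 1:
        return a[:, :, 0]
    if a.ndim == 4 and a.shape[2] == 1:
        return a[:, :, 0, :]
    return a
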
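"""Rigid affines and grid resampling.

World coordinates are in mm.  A grid's ``affine`` maps 0-based voxel indices
to world mm, with the world origin at the grid centre.  Subject motion is a
small rigid transform ``R`` mapping subject world coordinates to template
world coordinates.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import TransformError


def grid_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """Voxel-to-world affine with the world origin at the grid centre."""
    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(shape, dtype=float) - 1.0) / 2.0
    return affine


def rigid_affine(translation_mm, rotation_deg) -> np.ndarray:
    """4x4 rigid world transform: rotate about x, y, z (in deg), then translate."""
    rx, ry, rz = np.deg2rad(np.asarray(rotation_deg, dtype=float))
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    out = np.eye(4)
    out[:3, :3] = mz @ my @ mx
    out[:3, 3] = np.asarray(translation_mm, dtype=float)
    return out


def sample_rigid_jitter(rng: np.random.Generator,
                        trans_sd_mm: float = 0.5,
                        rot_sd_deg: float = 0.5) -> np.ndarray:
    """Small random rigid subject-to-template transform."""
    return rigid_affine(rng.normal(0.0, trans_sd_mm, size=3),
                        rng.normal(0.0, rot_sd_deg, size=3))


def _voxel_map(in_affine: np.ndarray, world: np.ndarray,
               out_affine: np.ndarray) -> np.ndarray:
    """Voxel-to-voxel map ``in_vox = M @ out_vox`` for ``x_in = world @ x_out``."""
    try:
        return np.linalg.inv(in_affine) @ world @ out_affine
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise TransformError(f"non-invertible affine: {exc}") from exc


def resample(data: np.ndarray, in_affine: np.ndarray, world: np.ndarray,
             out_affine: np.ndarray, out_shape: tuple[int, ...],
             order: int = 1) -> np.ndarray:
    """Resample ``data`` onto the output grid.

    ``world`` maps output-grid world coordinates into input-grid world
    coordinates (i.e. where in the input each output voxel samples from).
    ``order`` 1 = trilinear (images), 0 = nearest neighbour (masks/labels).
    """
    if not np.all(np.isfinite(world)):
        raise TransformError("affine contains non-finite entries")
    if abs(np.linalg.det(world[:3, :3])) < 1e-12:
        raise TransformError("singular world transform")
    vox = _voxel_map(in_affine, world, out_affine)
    if data.shape == tuple(out_shape) and np.allclose(vox, np.eye(4), atol=1e-12):
        return data.copy()
    out = ndimage.affine_transform(
        np.asarray(data, dtype=float), matrix=vox[:3, :3], offset=vox[:3, 3],
        output_shape=tuple(out_shape), order=order, mode="constant", cval=0.0,
        prefilter=order > 1)
    if order == 0:
        out = out.astype(data.dtype)
    return out
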
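"""Trilinear slicing (gather) and merging (scatter) between the cubic
intensity grid and Ewald-sphere detector slices.

A single pair of routines serves both the simulator and the reconstruction:
a tomogram sample for orientation r and pixel t reads the grid at
``R(q_r) @ qvec_t + center``; merging scatter-adds values back into the
8 neighbouring voxels with the same trilinear weights, so expand and
compress are exact adjoints.
"""

from __future__ import annotations

import numpy as np

from .exceptions import GeometryError

__all__ = ["slice_model", "merge_slices"]

_CORNERS = [(dx, dy, dz) for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)]


def _check_bounds(i0: np.ndarray, side: int, what: str) -> None:
    bad = (i0 < 0).any(axis=-1) | (i0 + 1 >= side).any(axis=-1)
    if bad.any():
        r, t = np.argwhere(bad)[0]
        raise GeometryError(
            f"{what}: rotated coordinate outside grid for orientation {r}, "
            f"pixel {t} (grid side {side})"
        )


def _corner_weight(f: np.ndarray, corner) -> np.ndarray:
    w = np.ones(f.shape[:-1])
    for axis, bit in enumerate(corner):
        w = w * (f[..., axis] if bit else 1.0 - f[..., axis])
    return w


def slice_model(grid: np.ndarray, rot_mats: np.ndarray, qvec: np.ndarray,
                chunk: int = 256) -> np.ndarray:
    """Trilinear gather of ``grid`` at rotated pixel coordinates.

    Parameters
    ----------
    grid : (M, M, M) array
    rot_mats : (R, 3, 3) rotation matrices
    qvec : (T, 3) pixel coordinates in voxel units, origin at grid center

    Returns
    -------
    (R, T) array of interpolated values.
    """
    side = grid.shape[0]
    center = side // 2
    flat = grid.ravel()
    R, T = len(rot_mats), len(qvec)
    out = np.empty((R, T))
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        pts = np.einsum("rij,tj->rti", rot_mats[lo:hi], qvec) + center
        i0 = np.floor(pts).astype(np.int64)
        _check_bounds(i0, side, "slice")
        f = pts - i0
        base = (i0[..., 0] * side + i0[..., 1]) * side + i0[..., 2]
        acc = np.zeros((hi - lo, T))
        for corner in _CORNERS:
            off = (corner[0] * side + corner[1]) * side + corner[2]
            acc += _corner_weight(f, corner) * flat[base + off]
        out[lo:hi] = acc
    return out


def merge_slices(values: np.ndarray, rot_mats: np.ndarray, qvec: np.ndarray,
                 side: int, chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear scatter-add of per-orientation slices into a cubic grid.

    Returns ``(num, wgt)`` grids: the weighted sum of deposited values and
    the accumulated trilinear weights.  The caller divides (where wgt > 0)
    to obtain the weighted-mean model.
    """
    center = side // 2
    nvox = side ** 3
    num = np.zeros(nvox)
    wgt = np.zeros(nvox)
    R = len(rot_mats)
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        pts = np.einsum("rij,tj->rti", rot_mats[lo:hi], qvec) + center
        i0 = np.floor(pts).astype(np.int64)
        _check_bounds(i0, side, "merge")
        f = pts - i0
        base = ((i0[..., 0] * side + i0[..., 1]) * side + i0[..., 2]).ravel()
        vals = values[lo:hi].ravel()
        for corner in _CORNERS:
            off = (corner[0] * side + corner[1]) * side + corner[2]
            w = _corner_weight(f, corner).ravel()
            idx = base + off
            num += np.bincount(idx, weights=w * vals, minlength=nvox)
            wgt += np.bincount(idx, weights=w, minlength=nvox)
    return num.reshape(side, side, side), wgt.reshape(side, side, side)
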
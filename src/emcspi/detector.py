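"""Detector geometry: Ewald-sphere pixel mapping, corrections, categories.

Every pixel of the square detector is mapped onto the Ewald sphere and
expressed in voxel units of the 3D intensity grid: with the pixel at grid
offset ``(x, y)`` (pixel units, beam axis through offset 0) and the sample
at distance ``D = detd / pixsize``, the unit scattering direction is
``s = (x, y, D) / |(x, y, D)|`` and the spatial frequency
``q = (s - zhat) / lambda``.  The voxel scaling is fixed so that the
edge-center pixel lands at radius ``detsize / 2``, which makes adjacent
central pixels about one voxel apart.

The per-pixel correction factor is the product of the flat-detector solid
angle (cos^3 theta for identical square pixels on a plane) and the Thomson
polarization factor, normalized to 1 on the beam axis.

Pixel categories: 0 = good (orients and merges), 1 = merge-only (outside
the inscribed circle, usually detector corners), 2 = bad (beamstop/dead,
never used).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import ExperimentConfig
from .exceptions import FormatError

__all__ = [
    "DetectorGeometry", "make_detector", "write_detector", "read_detector",
    "model_size",
]

GOOD, MERGE_ONLY, BAD = 0, 1, 2


@dataclass
class DetectorGeometry:
    """Per-pixel reciprocal-space geometry of a (possibly irregular) detector."""

    qvec: np.ndarray       # (num_pix, 3) voxel units
    corr: np.ndarray       # (num_pix,) polarization * solid-angle, 1 on axis
    category: np.ndarray   # (num_pix,) ints in {0, 1, 2}
    detd_px: float = 0.0   # detector distance in pixel units (0 if unknown)
    detsize: int = 0       # grid side for dense frame layout (0 if irregular)

    def __post_init__(self) -> None:
        self.qvec = np.asarray(self.qvec, dtype=np.float64).reshape(-1, 3)
        self.corr = np.asarray(self.corr, dtype=np.float64).ravel()
        self.category = np.asarray(self.category, dtype=np.int64).ravel()
        n = len(self.qvec)
        if len(self.corr) != n or len(self.category) != n:
            raise FormatError("qvec, corr and category lengths differ")
        if not np.isin(self.category, (GOOD, MERGE_ONLY, BAD)).all():
            raise FormatError("pixel categories must be in {0, 1, 2}")
        usable = self.category != BAD
        if np.any(self.corr[usable] <= 0):
            raise FormatError("corr must be > 0 for category 0/1 pixels")

    @property
    def num_pix(self) -> int:
        return len(self.qvec)

    def pixels(self, categories=(GOOD, MERGE_ONLY)) -> np.ndarray:
        """Indices of pixels whose category is in ``categories``."""
        return np.flatnonzero(np.isin(self.category, categories))

    @property
    def qmax(self) -> float:
        """Largest |qvec| over usable (category 0/1) pixels, in voxels."""
        sel = self.pixels()
        if len(sel) == 0:
            return 0.0
        return float(np.linalg.norm(self.qvec[sel], axis=1).max())


def make_detector(cfg: ExperimentConfig) -> DetectorGeometry:
    """Build the detector for a square grid, row-major pixel order."""
    n = cfg.detsize
    cx = n // 2  # axial pixel index; exact beam-axis pixel exists by choice
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    x = (ii - cx).astype(np.float64).ravel()
    y = (jj - cx).astype(np.float64).ravel()
    D = cfg.detd_px

    norm = np.sqrt(x * x + y * y + D * D)
    sx, sy, sz = x / norm, y / norm, D / norm
    lam = cfg.wavelength  # any unit: scaling below cancels it
    q = np.stack([sx / lam, sy / lam, (sz - 1.0) / lam], axis=1)

    # voxel scaling: edge-center point maps to radius detsize/2
    half = n / 2.0
    edge_norm = math.hypot(half, D)
    q_edge = math.sqrt((half / edge_norm) ** 2 + (D / edge_norm - 1.0) ** 2) / lam
    qvec = q * (half / q_edge)

    solid = (D / norm) ** 3
    if cfg.polarization == "x":
        pol = 1.0 - sx * sx
    elif cfg.polarization == "y":
        pol = 1.0 - sy * sy
    else:  # unpolarized
        pol = (1.0 + sz * sz) / 2.0
    corr = solid * pol
    corr /= corr[(cx * n) + cx]  # normalize to axial pixel (factor is 1 anyway)

    r = np.hypot(x, y)
    category = np.zeros(n * n, dtype=np.int64)
    category[r > n / 2.0] = MERGE_ONLY
    category[r < cfg.stoprad] = BAD
    if not np.any(category != BAD):
        warnings.warn("stoprad masks every pixel of the detector", stacklevel=2)
    return DetectorGeometry(qvec=qvec, corr=corr, category=category,
                            detd_px=D, detsize=n)


def model_size(det: DetectorGeometry) -> int:
    """Side of the cubic intensity grid holding every rotated pixel.

    Odd so that a center voxel exists, with a one-voxel interpolation
    margin: ``M = 2 * ceil(qmax) + 3``.
    """
    return 2 * int(math.ceil(det.qmax)) + 3


def write_detector(det: DetectorGeometry, path) -> None:
    """Write the ASCII detector file: header = pixel count, then
    ``qx qy qz corr category`` per line."""
    with open(path, "w") as fh:
        fh.write(f"{det.num_pix}\n")
        for (qx, qy, qz), c, cat in zip(det.qvec, det.corr, det.category):
            fh.write(f"{qx:.8e} {qy:.8e} {qz:.8e} {c:.8e} {cat:d}\n")


def read_detector(path, detsize: int = 0, detd_px: float = 0.0) -> DetectorGeometry:
    """Read an ASCII detector file written by :func:`write_detector`.

    ``detsize``/``detd_px`` are optional metadata not stored in the file
    (needed only for dense frame rendering).
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 1:
            raise FormatError("detector header must be a single pixel count")
        try:
            num_pix = int(header[0])
        except ValueError:
            raise FormatError(f"bad detector pixel count {header[0]!r}") from None
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(
                    f"detector line {lineno}: expected 5 columns, got {len(parts)}"
                )
            rows.append([float(p) for p in parts[:4]] + [int(parts[4])])
    if len(rows) != num_pix:
        raise FormatError(
            f"detector header says {num_pix} pixels but file has {len(rows)}"
        )
    arr = np.asarray(rows, dtype=np.float64).reshape(num_pix, 5)
    return DetectorGeometry(
        qvec=arr[:, :3], corr=arr[:, 3], category=arr[:, 4].astype(np.int64),
        detd_px=detd_px, detsize=detsize,
    )
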
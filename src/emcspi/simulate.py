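"""Data-stream simulator: phantom densities, 3D intensities, photon frames.

The chain mirrors a single-particle imaging experiment: an electron
density (a synthetic multi-blob phantom, or atoms from a PDB file) is
Fourier transformed to a 3D diffraction volume ``I(q) = |F[rho]|^2``; each
simulated frame then draws a uniform random orientation, slices the volume
on the Ewald sphere at the detector pixels, scales to the target mean
photon count, optionally jitters the incident fluence and adds a uniform
background, and draws Poisson photon counts which are stored sparsely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._interp import slice_model
from .detector import BAD, DetectorGeometry
from .exceptions import AliasingError
from .photons import SparsePhotonSet
from .rotations import quats_to_matrices, random_rotations

__all__ = [
    "DensityMap", "IntensityModel", "GroundTruth",
    "make_phantom_density", "density_from_pdb", "make_intensities",
    "simulate_frames",
]


@dataclass
class DensityMap:
    """Cubic electron-density grid; ``support_radius`` in nm."""

    grid: np.ndarray
    voxel_size: float
    support_radius: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("density grid must be cubic")
        if np.any(self.grid < 0):
            raise ValueError("density must be nonnegative")


@dataclass
class IntensityModel:
    """Cubic 3D diffraction-intensity grid, zero frequency at the center voxel."""

    grid: np.ndarray
    scale: float = 1.0  # photons per unit intensity at reference fluence

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError("intensity grid must be cubic")
        if self.grid.shape[0] % 2 == 0:
            raise ValueError("intensity grid side must be odd")
        if not np.isfinite(self.grid).all() or np.any(self.grid < 0):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def side(self) -> int:
        return self.grid.shape[0]


@dataclass
class GroundTruth:
    """Per-frame orientation and fluence factor used by the simulator."""

    true_quats: np.ndarray
    true_scales: np.ndarray


def make_phantom_density(R_p: float, voxel_size: float, n_blobs: int = 6,
                         seed: int = 0) -> DensityMap:
    """Random multi-blob phantom of radius ``R_p`` nm, apodized to zero at R_p.

    Gaussian blobs with random centers inside 0.8 R_p and random weights,
    multiplied by a raised-cosine window that vanishes at the support
    radius.  Deterministic for a given seed.
    """
    if R_p < 3 * voxel_size:
        raise ValueError("R_p must be at least 3 voxels for a resolvable phantom")
    rng = np.random.default_rng(seed)
    r_vox = R_p / voxel_size
    half = int(math.ceil(r_vox)) + 2
    side = 2 * half + 1
    ax = (np.arange(side) - half) * voxel_size
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = np.zeros((side, side, side))
    width = R_p / 3.0
    for _ in range(n_blobs):
        center = rng.uniform(-0.8 * R_p, 0.8 * R_p, size=3)
        while np.linalg.norm(center) > 0.8 * R_p:
            center = rng.uniform(-0.8 * R_p, 0.8 * R_p, size=3)
        weight = rng.uniform(0.5, 1.5)
        w = width * rng.uniform(0.6, 1.2)
        r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        rho += weight * np.exp(-r2 / (2 * w * w))
    r = np.sqrt(X * X + Y * Y + Z * Z)
    window = np.where(r < R_p, 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / R_p, 1.0))), 0.0)
    return DensityMap(grid=rho * window, voxel_size=voxel_size, support_radius=R_p)


# electron counts for the common elements of biomolecules
_ELECTRONS = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def density_from_pdb(path, voxel_size: float, atom_sigma: float = 0.2,
                     pad: int = 3) -> DensityMap:
    """Convenience wrapper: atoms from a PDB file splatted as Gaussian
    spheres weighted by electron count.  ``voxel_size`` and ``atom_sigma``
    in nm."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("mol", str(path))
    coords, weights = [], []
    for atom in structure.get_atoms():
        coords.append(atom.coord / 10.0)  # Angstrom -> nm
        weights.append(_ELECTRONS.get(atom.element.strip().upper(), 6))
    coords = np.asarray(coords)
    weights = np.asarray(weights, dtype=np.float64)
    coords -= coords.mean(axis=0)
    radius = float(np.linalg.norm(coords, axis=1).max())
    half = int(math.ceil(radius / voxel_size)) + pad
    side = 2 * half + 1
    rho = np.zeros((side, side, side))
    span = int(math.ceil(3 * atom_sigma / voxel_size))
    offs = np.arange(-span, span + 1)
    for (cx, cy, cz), w in zip(coords, weights):
        i, j, k = (int(round(c / voxel_size)) + half for c in (cx, cy, cz))
        gx = np.exp(-((offs * voxel_size + i * voxel_size - half * voxel_size - cx) ** 2)
                    / (2 * atom_sigma ** 2))
        gy = np.exp(-((offs * voxel_size + j * voxel_size - half * voxel_size - cy) ** 2)
                    / (2 * atom_sigma ** 2))
        gz = np.exp(-((offs * voxel_size + k * voxel_size - half * voxel_size - cz) ** 2)
                    / (2 * atom_sigma ** 2))
        blob = w * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        rho[i - span:i + span + 1, j - span:j + span + 1, k - span:k + span + 1] += blob
    return DensityMap(grid=rho, voxel_size=voxel_size,
                      support_radius=radius + 3 * atom_sigma)


def make_intensities(density: DensityMap, model_side: int,
                     lowpass_sd: float | str | None = "auto") -> IntensityModel:
    """Diffraction intensities ``|F[rho]|^2`` on an odd cubic grid.

    The density is embedded centered in the ``model_side``^3 field of view
    and a Gaussian low-pass filter emulating the atomic form-factor
    fall-off is applied in reciprocal space (``lowpass_sd`` in frequency
    index units from the grid center; ``"auto"`` = half the edge frequency,
    ``None`` disables).  The returned grid has its zero frequency at the
    center voxel and exact Friedel symmetry I(q) = I(-q).
    """
    M = int(model_side)
    if M % 2 == 0:
        raise ValueError("model_side must be odd")
    support_vox = 2.0 * density.support_radius / density.voxel_size
    if support_vox > M:
        raise AliasingError(
            f"particle support ({support_vox:.1f} voxels) exceeds the "
            f"field of view ({M} voxels)"
        )
    side = density.grid.shape[0]
    if side > M:
        raise AliasingError("density grid larger than the intensity grid")
    rho = np.zeros((M, M, M))
    lo = (M - side) // 2
    rho[lo:lo + side, lo:lo + side, lo:lo + side] = density.grid

    F = np.fft.fftn(rho)
    if lowpass_sd is not None:
        sd = (M / 2.0) / 2.0 if lowpass_sd == "auto" else float(lowpass_sd)
        freq = np.fft.fftfreq(M) * M  # index units
        f2 = (freq[:, None, None] ** 2 + freq[None, :, None] ** 2
              + freq[None, None, :] ** 2)
        F = F * np.exp(-f2 / (2.0 * sd * sd))
    intens = np.fft.fftshift(np.abs(F) ** 2)
    intens = 0.5 * (intens + intens[::-1, ::-1, ::-1])  # exact Friedel symmetry
    return IntensityModel(grid=intens)


def simulate_frames(model: IntensityModel, det: DetectorGeometry,
                    num_data: int, mean_count: float,
                    fluence_spread_frac: float = 0.0,
                    background_mean: float = 0.0, seed: int = 0,
                    quats: np.ndarray | None = None,
                    ) -> tuple[SparsePhotonSet, GroundTruth]:
    """Poisson-sample ``num_data`` sparse frames from the intensity model.

    Per frame the expected count at pixel t is
    ``mu_t = phi_d * s * corr_t * W(R_d q_t) + background_mean / num_pix``
    where the global scale ``s`` is calibrated so that the category-0/1
    photon-count expectation equals ``mean_count`` at unit fluence, and
    ``phi_d`` is Gaussian with mean 1 and sd ``fluence_spread_frac``
    truncated at zero.  Category-2 pixels receive no photons.  The output
    is deterministic for a given seed; ``quats`` is a test hook that fixes
    the per-frame orientations.
    """
    if mean_count <= 0:
        raise ValueError("mean_count must be > 0")
    rng = np.random.default_rng(seed)
    if quats is None:
        quats = random_rotations(num_data, rng)
    else:
        quats = np.asarray(quats, dtype=np.float64).reshape(num_data, 4)
    mats = quats_to_matrices(quats)

    if fluence_spread_frac > 0:
        phi = rng.normal(1.0, fluence_spread_frac, size=num_data)
        while np.any(phi <= 0):
            bad = phi <= 0
            phi[bad] = rng.normal(1.0, fluence_spread_frac, size=int(bad.sum()))
    else:
        phi = np.ones(num_data)

    usable = det.pixels()                       # category 0 and 1
    qv, corr = det.qvec[usable], det.corr[usable]
    frames_dense = np.zeros((num_data, det.num_pix), dtype=np.int64)
    chunk = max(1, int(2e7) // max(1, len(usable)))
    # calibration: photons per frame at phi = 1 averaged over drawn orientations
    total_unscaled = 0.0
    raw = []
    for lo in range(0, num_data, chunk):
        hi = min(lo + chunk, num_data)
        w = slice_model(model.grid, mats[lo:hi], qv) * corr
        raw.append(w)
        total_unscaled += float(w.sum())
    if total_unscaled <= 0:
        scale = 0.0
    else:
        scale = mean_count * num_data / total_unscaled
    bg = background_mean / det.num_pix
    row = 0
    for w in raw:
        mu = scale * phi[row:row + len(w), None] * w + bg
        frames_dense[row:row + len(w), usable] = rng.poisson(mu)
        row += len(w)
    ps = SparsePhotonSet.from_dense(frames_dense, num_pix=det.num_pix)
    return ps, GroundTruth(true_quats=quats, true_scales=phi)
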
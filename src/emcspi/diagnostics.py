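"""Convergence diagnostics for EMC reconstructions.

Four per-iteration quantities: the r.m.s. change per voxel between
successive 3D models; the mutual information between frames and
orientations under the current posterior (nats per frame, bounded by the
entropy of the rotation sampling); the EM surrogate average log-likelihood;
and the per-frame most-likely-orientation matrix, block-sorted for
rendering.
"""

from __future__ import annotations

import numpy as np

from .emc import ProbabilityMatrix, ScaleFactors, TomogramSet, W_FLOOR
from .photons import SparsePhotonSet
from .simulate import IntensityModel

__all__ = [
    "rms_change", "mutual_information", "avg_loglike", "marginal_loglike",
    "orientation_matrix", "aligned_correlation",
]


def rms_change(w_old: IntensityModel | np.ndarray,
               w_new: IntensityModel | np.ndarray) -> float:
    """Root-mean-squared per-voxel difference of two models."""
    a = w_old.grid if isinstance(w_old, IntensityModel) else np.asarray(w_old)
    b = w_new.grid if isinstance(w_new, IntensityModel) else np.asarray(w_new)
    if a.shape != b.shape:
        raise ValueError(f"model shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mutual_information(P: np.ndarray | ProbabilityMatrix,
                       prior: np.ndarray | None = None) -> float:
    """I(K; Omega) = <sum_r P_dr ln(P_dr / P_r)>_d in nats per frame.

    Vanishes for a uniform posterior and approaches the sampling entropy
    (ln M_rot for a uniform prior) when every frame fits one orientation.
    """
    p = P.P if isinstance(P, ProbabilityMatrix) else np.asarray(P, dtype=np.float64)
    m_rot = p.shape[1]
    if prior is None:
        prior = np.full(m_rot, 1.0 / m_rot)
    prior = np.asarray(prior, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * (np.log(p) - np.log(prior)[None, :])
    terms[p == 0] = 0.0  # 0 ln 0 = 0
    return float(np.mean(terms.sum(axis=1)))


def avg_loglike(P: ProbabilityMatrix, ps: SparsePhotonSet,
                tomos: TomogramSet,
                scales: ScaleFactors | None = None) -> float:
    """EM surrogate Q = <sum_r P_dr sum_t [K_dt ln W_rt - W_rt]>_d,
    model-independent constants dropped.  Category-0 pixels only,
    matching the E-step."""
    from .emc import _log_r

    logR = _log_r(tomos, ps, scales)
    return float(np.mean(np.sum(P.P * logR, axis=1)))


def marginal_loglike(P: ProbabilityMatrix,
                     prior: np.ndarray | None = None) -> float:
    """Marginal log-likelihood <ln sum_r w_r R_dr>_d (same dropped
    constants as the surrogate); available as an extra diagnostic."""
    logR = P.logR
    m_rot = logR.shape[1]
    if prior is None:
        prior = np.full(m_rot, 1.0 / m_rot)
    shift = logR.max(axis=1, keepdims=True)
    lse = shift.ravel() + np.log(
        np.sum(np.exp(logR - shift) * prior[None, :], axis=1)
    )
    return float(np.mean(lse))


def aligned_correlation(recovered: IntensityModel | np.ndarray,
                        truth: IntensityModel | np.ndarray,
                        rot_mats: np.ndarray,
                        shell: tuple[float, float] = (0.1, 0.8),
                        subsample: int = 1) -> float:
    """Best Pearson correlation between two models over a set of rotations.

    A reconstruction recovers the diffraction volume only up to a global
    rotation, so the recovered model is compared with the truth after
    rotating by each candidate in ``rot_mats`` (exhaustive search; typically
    the rotation sampling used in the run).  The correlation is evaluated
    on voxels in the radial shell ``shell`` (fractions of the edge radius
    M/2), which excludes the unconstrained center and the sparsely covered
    corners.  ``subsample`` keeps every k-th shell voxel for speed.
    """
    from scipy.ndimage import map_coordinates

    rec = recovered.grid if isinstance(recovered, IntensityModel) else np.asarray(recovered)
    tru = truth.grid if isinstance(truth, IntensityModel) else np.asarray(truth)
    if rec.shape != tru.shape:
        raise ValueError("model shapes differ")
    side = rec.shape[0]
    center = side // 2
    ax = np.arange(side) - center
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X * X + Y * Y + Z * Z)
    lo, hi = shell[0] * (side / 2), shell[1] * (side / 2)
    sel = np.flatnonzero(((r >= lo) & (r <= hi)).ravel())[::subsample]
    coords = np.stack([X.ravel()[sel], Y.ravel()[sel], Z.ravel()[sel]])
    t_vals = tru.ravel()[sel].astype(np.float64)
    t_vals -= t_vals.mean()
    t_norm = np.linalg.norm(t_vals)
    best = -1.0
    for mat in rot_mats:
        pts = mat @ coords + center
        r_vals = map_coordinates(rec, pts, order=1, mode="nearest")
        r_vals -= r_vals.mean()
        denom = np.linalg.norm(r_vals) * t_norm
        if denom > 0:
            best = max(best, float(r_vals @ t_vals / denom))
    return best


def orientation_matrix(history: np.ndarray, blocks: list[tuple[int, int]]
                       ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sort the most-likely-orientation matrix for rendering.

    ``history`` is (frames, iterations); ``blocks`` lists half-open column
    ranges sharing one rotation sampling.  Within each block the rows are
    permuted (stably) so the block's final column is ascending; the values
    are unchanged.  Returns the sorted matrix and the per-block row
    permutations.
    """
    history = np.asarray(history)
    if history.ndim != 2 or history.size == 0:
        raise ValueError("history must be a nonempty (frames, iterations) matrix")
    out = np.empty_like(history)
    perms = []
    for start, stop in blocks:
        if not 0 <= start < stop <= history.shape[1]:
            raise ValueError(f"bad block range ({start}, {stop})")
        perm = np.argsort(history[:, stop - 1], kind="stable")
        out[:, start:stop] = history[perm, start:stop]
        perms.append(perm)
    return out, perms
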
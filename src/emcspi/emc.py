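"""The expand-maximize-compress iteration.

One EMC pass: *expand* slices the current 3D model into per-orientation
tomograms on the detector pixels; the *E-step* evaluates the Poisson
log-likelihood of every frame against every tomogram and normalizes over
orientations (optionally annealed by an exponent beta < 1); the *M-step*
replaces each tomogram by the probability-weighted average of the frames;
*compress* merges the updated tomograms back into the 3D grid.  Optional
per-frame scale factors absorb pulse-to-pulse fluence variation.

Category-0 pixels drive the orientation posterior; category-1 pixels are
excluded from the E-step but still merged; category-2 pixels are ignored
throughout.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._interp import merge_slices, slice_model
from .config import ExperimentConfig
from .detector import GOOD, MERGE_ONLY, DetectorGeometry, model_size
from .exceptions import EmcspiError
from .photons import SparsePhotonSet
from .rotations import RotationSampling, sample_rotations
from .simulate import IntensityModel

__all__ = [
    "TomogramSet", "ProbabilityMatrix", "ScaleFactors", "EmcState",
    "expand", "e_step", "m_step", "compress", "update_scales",
    "run_emc", "run_tomogram_em", "beta_at",
]

W_FLOOR = 1e-20  # floor inside logarithms for zero-intensity pixels


@dataclass
class TomogramSet:
    """Per-orientation predicted mean intensities on the usable pixels.

    ``values[r, t]`` is W_rt (correction factor included) for pixel
    ``pixels[t]`` of the detector; ``estep_cols`` marks the category-0
    columns used for orientation determination.
    """

    values: np.ndarray        # (R, T01)
    pixels: np.ndarray        # (T01,) detector pixel indices (categories 0/1)
    estep_cols: np.ndarray    # (T01,) bool, True where category == 0
    corr: np.ndarray          # (T01,) correction factors of those pixels
    observed: np.ndarray | None = None  # (R,) bool, False = no posterior mass

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(self.values).all() or np.any(self.values < 0):
            raise ValueError("tomogram values must be finite and nonnegative")


@dataclass
class ProbabilityMatrix:
    """Unnormalized log-likelihoods and the annealed orientation posterior."""

    logR: np.ndarray  # (D, R) log R_dr up to per-frame constants
    P: np.ndarray     # (D, R) posterior, rows sum to 1
    beta: float

    @property
    def most_likely(self) -> np.ndarray:
        """Per-frame argmax_r P_dr (ties: lowest index)."""
        return np.argmax(self.P, axis=1)


@dataclass
class ScaleFactors:
    """Per-frame fluence factors, gauge-fixed to mean 1."""

    phi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64).ravel()
        if np.any(self.phi <= 0):
            raise ValueError("scale factors must be positive")


@dataclass
class EmcState:
    """Mutable state of a reconstruction run."""

    model: IntensityModel
    sampling: RotationSampling
    iteration: int = 0
    beta: float = 1.0
    scales: ScaleFactors | None = None
    history: list = field(default_factory=list)


# ------------------------------------------------------------------ steps

def expand(model: IntensityModel, sampling: RotationSampling,
           det: DetectorGeometry) -> TomogramSet:
    """Slice the 3D model into tomograms W_rt = corr_t * W(R_r q_t)."""
    pixels = det.pixels((GOOD, MERGE_ONLY))
    qv = det.qvec[pixels]
    corr = det.corr[pixels]
    values = slice_model(model.grid, sampling.matrices, qv) * corr
    np.clip(values, 0.0, None, out=values)  # interpolation can dip below 0
    return TomogramSet(
        values=values, pixels=pixels,
        estep_cols=det.category[pixels] == GOOD, corr=corr,
    )


def _log_r(tomos: TomogramSet, ps: SparsePhotonSet,
           scales: ScaleFactors | None) -> np.ndarray:
    """log R_dr = sum_t [K_dt ln(phi_d W_rt) - phi_d W_rt] up to per-frame
    constants (the K! term and the r-independent K ln phi term drop)."""
    cols = tomos.pixels[tomos.estep_cols]
    W = tomos.values[:, tomos.estep_cols]
    lnW = np.log(np.maximum(W, W_FLOOR))
    K = ps.to_csr(columns=cols)
    logR = np.asarray(K @ lnW.T)             # (D, R)
    wsum = W.sum(axis=1)                     # (R,)
    phi = scales.phi if scales is not None else np.ones(ps.num_data)
    logR -= phi[:, None] * wsum[None, :]
    return logR


def _normalize(logR: np.ndarray, beta: float,
               weights: np.ndarray | None) -> np.ndarray:
    """Annealed posterior P_dr from log R_dr, computed in the log domain."""
    logP = beta * logR
    if weights is not None:
        logP = logP + np.log(weights)[None, :]
    logP -= logP.max(axis=1, keepdims=True)
    P = np.exp(logP)
    norm = P.sum(axis=1, keepdims=True)
    if np.any(norm == 0) or not np.isfinite(norm).all():
        bad = int(np.flatnonzero((norm == 0) | ~np.isfinite(norm))[0])
        raise EmcspiError(f"posterior underflow for frame {bad}")
    return P / norm


def e_step(tomos: TomogramSet, ps: SparsePhotonSet,
           scales: ScaleFactors | None = None, beta: float = 1.0,
           weights: np.ndarray | None = None) -> ProbabilityMatrix:
    """Poisson E-step with deterministic-annealing exponent ``beta``.

    ``weights`` is the orientation prior w_r (uniform when omitted).
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    logR = _log_r(tomos, ps, scales)
    return ProbabilityMatrix(logR=logR, P=_normalize(logR, beta, weights),
                             beta=beta)


def m_step(P: ProbabilityMatrix, ps: SparsePhotonSet, tomos: TomogramSet,
           scales: ScaleFactors | None = None) -> TomogramSet:
    """Update rule W'_rt = sum_d P_dr K_dt / sum_d P_dr phi_d.

    Orientations with zero posterior mass are flagged unobserved and
    excluded from the subsequent compress.
    """
    K = ps.to_csr(columns=tomos.pixels)
    num = np.asarray((K.T @ P.P).T)          # (R, T01)
    phi = scales.phi if scales is not None else np.ones(ps.num_data)
    den = P.P.T @ phi                        # (R,)
    observed = den > 0
    values = np.zeros_like(num)
    values[observed] = num[observed] / den[observed, None]
    return TomogramSet(
        values=values, pixels=tomos.pixels, estep_cols=tomos.estep_cols,
        corr=tomos.corr, observed=observed,
    )


def compress(tomos: TomogramSet, sampling: RotationSampling,
             det: DetectorGeometry, side: int,
             prev: IntensityModel | None = None,
             keep_uncovered: bool = True) -> IntensityModel:
    """Merge tomograms into the 3D grid (trilinear scatter, weighted mean).

    The correction factor is divided out before merging so the model is
    correction-free.  Voxels that receive no weight keep the previous
    model's value when ``keep_uncovered`` (else zero).
    """
    mats = sampling.matrices
    values = tomos.values / tomos.corr
    if tomos.observed is not None and not tomos.observed.all():
        sel = tomos.observed
        mats, values = mats[sel], values[sel]
    qv = det.qvec[tomos.pixels]
    num, wgt = merge_slices(values, mats, qv, side)
    covered = wgt > 0
    grid = np.zeros((side, side, side))
    grid[covered] = num[covered] / wgt[covered]
    if keep_uncovered and prev is not None:
        grid[~covered] = prev.grid[~covered]
    np.clip(grid, 0.0, None, out=grid)
    return IntensityModel(grid=grid, scale=prev.scale if prev else 1.0)


def update_scales(P: ProbabilityMatrix, ps: SparsePhotonSet,
                  tomos: TomogramSet) -> ScaleFactors:
    """Fluence update phi'_d = sum_t K_dt / sum_r P_dr sum_t W_rt,
    renormalized to mean 1 (the gauge freedom sits in the model scale)."""
    cols = tomos.estep_cols
    K_tot = np.asarray(ps.to_csr(columns=tomos.pixels[cols]).sum(axis=1)).ravel()
    wsum = tomos.values[:, cols].sum(axis=1)   # (R,)
    pred = P.P @ wsum                          # (D,)
    if np.any(pred <= 0):
        bad = int(np.flatnonzero(pred <= 0)[0])
        raise EmcspiError(f"zero predicted intensity for frame {bad}")
    phi = K_tot / pred
    phi = np.maximum(phi, 1e-12)
    return ScaleFactors(phi=phi / phi.mean())


def beta_at(iteration: int, beta_start: float, beta_jump: float,
            beta_period: int) -> float:
    """Annealing exponent at 1-based ``iteration``: beta_start multiplied
    by beta_jump every beta_period iterations, capped at 1."""
    steps = max(0, (iteration - 1) // beta_period)
    return min(1.0, beta_start * beta_jump ** steps)


# ------------------------------------------------------------------ driver

_MODEL_RE = re.compile(r"intensities_(\d+)\.bin$")


def _find_last_iteration(output_dir: Path) -> int:
    last = 0
    if output_dir.is_dir():
        for p in output_dir.iterdir():
            m = _MODEL_RE.match(p.name)
            if m:
                last = max(last, int(m.group(1)))
    return last


def _load_model(path: Path, side: int) -> IntensityModel:
    grid = np.fromfile(path, dtype=np.float64)
    if grid.size != side ** 3:
        raise EmcspiError(
            f"model file {path} has {grid.size} voxels, expected {side ** 3}"
        )
    return IntensityModel(grid=grid.reshape(side, side, side))


def run_emc(cfg: ExperimentConfig, det: DetectorGeometry, ps: SparsePhotonSet,
            iterations: int, resume: bool = False,
            start_model: IntensityModel | None = None,
            sampling: RotationSampling | None = None,
            output_dir: str | Path | None = None,
            friedel: bool = True, keep_uncovered: bool = True,
            quiet: bool = True) -> EmcState:
    """Run ``iterations`` EMC passes, writing per-iteration outputs.

    Each pass runs expand -> E-step -> (scale update) -> M-step -> compress
    and appends a diagnostics row to ``EMC.log`` in the output folder.  The
    model is written as ``intensities_NNN.bin`` (dense row-major float64)
    and the per-frame most likely orientations accumulate in
    ``mostlikely.bin`` with a text sidecar recording block boundaries.  On
    ``resume``, the run continues from the largest iteration suffix found.
    """
    from .diagnostics import avg_loglike, mutual_information, rms_change

    out = Path(output_dir) if output_dir is not None else Path(cfg.output_folder)
    out.mkdir(parents=True, exist_ok=True)
    side = model_size(det)
    if sampling is None:
        sampling = sample_rotations(cfg.num_div)

    start_iter = 0
    if resume:
        start_iter = _find_last_iteration(out)
        if start_iter == 0:
            raise EmcspiError(f"resume requested but no model files in {out}")
        model = _load_model(out / f"intensities_{start_iter:03d}.bin", side)
    elif start_model is not None:
        model = start_model
    else:
        # random positive start around the mean photon density
        rng = np.random.default_rng(cfg.seed)
        n_usable = max(1, len(det.pixels()))
        mean_density = ps.total_photons / max(1, ps.num_data) / n_usable
        grid = rng.uniform(0.0, 2.0 * max(mean_density, 1e-10),
                           size=(side, side, side))
        model = IntensityModel(grid=grid)

    state = EmcState(model=model, sampling=sampling, iteration=start_iter)
    log_path = out / "EMC.log"
    if not resume or not log_path.exists():
        with open(log_path, "w") as fh:
            fh.write("# iter beta m_rot rms_change mutual_info avg_loglike"
                     " walltime\n")
    ml_rows = []
    scales = None
    if cfg.need_scaling:
        scales = ScaleFactors(phi=np.ones(ps.num_data))

    for it in range(start_iter + 1, start_iter + 1 + iterations):
        t0 = time.perf_counter()
        beta = beta_at(it, cfg.beta_start, cfg.beta_jump, cfg.beta_period)
        tomos = expand(state.model, sampling, det)
        prob = e_step(tomos, ps, scales=scales, beta=beta,
                      weights=sampling.weights)
        if cfg.need_scaling:
            scales = update_scales(prob, ps, tomos)
        new_tomos = m_step(prob, ps, tomos, scales=scales)
        new_model = compress(new_tomos, sampling, det, side, prev=state.model,
                             keep_uncovered=keep_uncovered)
        if friedel:
            g = new_model.grid
            new_model = IntensityModel(
                grid=0.5 * (g + g[::-1, ::-1, ::-1]), scale=new_model.scale)

        rms = rms_change(state.model, new_model)
        mi = mutual_information(prob.P, sampling.weights)
        ll = float(np.mean(np.sum(prob.P * prob.logR, axis=1)))
        wall = time.perf_counter() - t0
        record = {
            "iteration": it, "beta": beta, "m_rot": len(sampling),
            "rms_change": rms, "mutual_info": mi, "avg_loglike": ll,
            "most_likely": prob.most_likely, "walltime": wall,
        }
        state.history.append(record)
        state.model = new_model
        state.iteration = it
        state.beta = beta
        state.scales = scales
        ml_rows.append(prob.most_likely.astype(np.int32))

        new_model.grid.tofile(out / f"intensities_{it:03d}.bin")
        with open(log_path, "a") as fh:
            fh.write(f"{it} {beta:.6g} {len(sampling)} {rms:.8e} "
                     f"{mi:.8e} {ll:.8e} {wall:.3f}\n")
        if not quiet:
            print(f"iter {it:3d}  beta={beta:.4g}  rms={rms:.4e}  "
                  f"MI={mi:.4f}  LL={ll:.6e}  ({wall:.1f}s)")

    _write_most_likely(out, ml_rows, len(sampling), resume)
    return state


def _write_most_likely(out: Path, rows: list, m_rot: int, resume: bool) -> None:
    """Append most-likely-orientation columns to mostlikely.bin and record
    the rotation-sampling block in the text sidecar."""
    if not rows:
        return
    new = np.stack(rows, axis=1)  # (frames, new_iters)
    bin_path = out / "mostlikely.bin"
    meta_path = out / "mostlikely.txt"
    if resume and bin_path.exists() and meta_path.exists():
        frames, cols = _read_ml_meta(meta_path)
        old = np.fromfile(bin_path, dtype=np.int32).reshape(frames, cols)
        new = np.concatenate([old, new], axis=1)
    new.astype(np.int32).tofile(bin_path)
    _append_ml_meta(meta_path, new.shape, m_rot, len(rows[0]), resume)


def _read_ml_meta(meta_path: Path):
    with open(meta_path) as fh:
        first = fh.readline().split()
    return int(first[1]), int(first[2])


def _append_ml_meta(meta_path: Path, shape, m_rot: int, frames: int,
                    resume: bool) -> None:
    blocks = []
    if resume and meta_path.exists():
        with open(meta_path) as fh:
            for line in fh:
                if line.startswith("block"):
                    blocks.append(line.strip())
    start = 0
    if blocks:
        start = int(blocks[-1].split()[2])
    blocks.append(f"block {start} {shape[1]} m_rot={m_rot}")
    with open(meta_path, "w") as fh:
        fh.write(f"shape {shape[0]} {shape[1]}\n")
        for b in blocks:
            fh.write(b + "\n")


# -------------------------------------------------------- tomogram-EM mode

def run_tomogram_em(K: np.ndarray, W0: np.ndarray, iterations: int,
                    beta: float = 1.0,
                    weights: np.ndarray | None = None):
    """Pure mixture EM on fixed tomograms (compress/expand bypassed).

    ``K`` is a dense (frames, pixels) count matrix and ``W0`` the (R,
    pixels) initial tomograms.  Returns the final tomograms and the
    per-iteration history of the EM surrogate Q (Poisson expected complete
    log-likelihood per frame), which the EM theorem makes non-decreasing
    at beta = 1.
    """
    K = np.asarray(K, dtype=np.float64)
    W = np.asarray(W0, dtype=np.float64).copy()
    q_hist = []
    for _ in range(iterations):
        lnW = np.log(np.maximum(W, W_FLOOR))
        logR = K @ lnW.T - W.sum(axis=1)[None, :]
        P = _normalize(logR, beta, weights)
        q_hist.append(float(np.mean(np.sum(P * logR, axis=1))))
        den = P.sum(axis=0)
        W = (P.T @ K) / np.maximum(den, 1e-300)[:, None]
    return W, q_hist
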
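"""Quasi-uniform sampling of the rotation group by 600-cell refinement.

Rotations are represented by unit quaternions (scalar first).  The regular
600-cell has 120 unit-quaternion vertices, 720 edges and 600 tetrahedral
cells; subdividing each cell with the level-n barycentric lattice, projecting
the points onto the unit 3-sphere and identifying antipodes (q and -q are
the same rotation) yields exactly ``10 (5 n^3 + n)`` rotation samples whose
covering radius shrinks like 1/n.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import FormatError

__all__ = [
    "RotationSampling", "num_samples", "sample_rotations", "quat_to_matrix",
    "quats_to_matrices", "quat_multiply", "random_rotations",
    "write_quaternions", "read_quaternions",
]


@dataclass
class RotationSampling:
    """A set of unit quaternions with prior weights summing to 1."""

    level: int
    quats: np.ndarray    # (M, 4) scalar-first unit quaternions
    weights: np.ndarray  # (M,) positive, sum 1

    def __post_init__(self) -> None:
        self.quats = np.asarray(self.quats, dtype=np.float64).reshape(-1, 4)
        self.weights = np.asarray(self.weights, dtype=np.float64).ravel()
        if len(self.weights) != len(self.quats):
            raise ValueError("weights and quats lengths differ")

    def __len__(self) -> int:
        return len(self.quats)

    @property
    def matrices(self) -> np.ndarray:
        return quats_to_matrices(self.quats)


def num_samples(n: int) -> int:
    """Number of rotation samples at refinement level ``n``: 10 (5 n^3 + n)."""
    if n < 1:
        raise ValueError("refinement level must be >= 1")
    return 10 * (5 * n ** 3 + n)


# ---------------------------------------------------------------- 600-cell

@functools.lru_cache(maxsize=1)
def _cell_structure():
    """Vertices (120, 4) and the 600 tetrahedral cells (vertex index tuples)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = []
    for axis in range(4):
        for sign in (1.0, -1.0):
            v = [0.0] * 4
            v[axis] = sign
            verts.append(v)
    for signs in itertools.product((0.5, -0.5), repeat=4):
        verts.append(list(signs))
    base = (phi / 2.0, 0.5, 1.0 / (2.0 * phi), 0.0)
    for perm in itertools.permutations(range(4)):
        # keep even permutations only
        inversions = sum(
            1 for i in range(4) for j in range(i + 1, 4) if perm[i] > perm[j]
        )
        if inversions % 2:
            continue
        for signs in itertools.product((1.0, -1.0), repeat=3):
            v = [0.0] * 4
            nz = 0
            for pos, idx in enumerate(perm):
                val = base[pos]
                if val != 0.0:
                    v[idx] = signs[nz] * val
                    nz += 1
            verts.append(v)
    verts = np.unique(np.round(np.asarray(verts), 12), axis=0)
    assert verts.shape == (120, 4)

    # edges join vertices with dot product cos(36 deg) = phi/2
    dots = verts @ verts.T
    adj = dots > 0.7
    np.fill_diagonal(adj, False)
    assert (adj.sum(1) == 12).all()

    neighbors = [set(np.flatnonzero(adj[i])) for i in range(120)]
    cells = []
    for a in range(120):
        na = {b for b in neighbors[a] if b > a}
        for b in sorted(na):
            common_ab = na & neighbors[b]
            for c in sorted(common_ab):
                if c <= b:
                    continue
                for d in sorted(common_ab & neighbors[c]):
                    if d > c:
                        cells.append((a, b, c, d))
    assert len(cells) == 600
    return verts, np.asarray(cells, dtype=np.int64)


def _canonicalize(quats: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Pick the antipodal representative whose first nonzero component > 0."""
    q = quats.copy()
    sign = np.zeros(len(q))
    for col in range(4):
        undecided = sign == 0
        if not undecided.any():
            break
        comp = q[undecided, col]
        s = np.where(np.abs(comp) > tol, np.sign(comp), 0.0)
        sign[undecided] = s
    sign[sign == 0] = 1.0
    return q * sign[:, None]


def sample_rotations(n: int, weight_policy: str = "uniform") -> RotationSampling:
    """Level-``n`` refinement of the 600-cell, antipodes identified.

    ``weight_policy`` selects the prior weights; ``"uniform"`` (the default,
    matching a uniform orientation prior) is currently the only policy.
    """
    if n < 1:
        raise ValueError("refinement level must be >= 1")
    if weight_policy != "uniform":
        raise ValueError(f"unknown weight policy {weight_policy!r}")
    verts, cells = _cell_structure()

    # barycentric lattice i+j+k+l = n on each tetrahedral cell
    bary = np.asarray(
        [
            (i, j, k, n - i - j - k)
            for i in range(n + 1)
            for j in range(n + 1 - i)
            for k in range(n + 1 - i - j)
        ],
        dtype=np.float64,
    ) / n
    corner_sets = verts[cells]                       # (600, 4, 4)
    pts = np.einsum("bi,cij->cbj", bary, corner_sets)
    pts = pts.reshape(-1, 4)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts = _canonicalize(pts)
    pts = np.unique(np.round(pts, 9), axis=0)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    expected = num_samples(n)
    if len(pts) != expected:
        raise RuntimeError(
            f"refinement produced {len(pts)} samples, expected {expected}"
        )
    weights = np.full(len(pts), 1.0 / len(pts))
    return RotationSampling(level=n, quats=pts, weights=weights)


# ------------------------------------------------------------- quaternions

def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product of scalar-first quaternions."""
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a scalar-first unit quaternion (renormalized)."""
    return quats_to_matrices(np.asarray(q, dtype=np.float64).reshape(1, 4))[0]


def quats_to_matrices(quats: np.ndarray) -> np.ndarray:
    """Vectorized quaternion -> proper-orthogonal matrix map, (M,4) -> (M,3,3)."""
    q = np.asarray(quats, dtype=np.float64).reshape(-1, 4)
    norm = np.linalg.norm(q, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero quaternion has no rotation matrix")
    q = q / norm
    w, x, y, z = q.T
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - z * w)
    m[:, 0, 2] = 2 * (x * z + y * w)
    m[:, 1, 0] = 2 * (x * y + z * w)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - x * w)
    m[:, 2, 0] = 2 * (x * z - y * w)
    m[:, 2, 1] = 2 * (y * z + x * w)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def random_rotations(num: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternions via the 3-uniform-deviates construction."""
    u1, u2, u3 = rng.random((3, num))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    t2, t3 = 2 * np.pi * u2, 2 * np.pi * u3
    return np.stack(
        [a * np.sin(t2), a * np.cos(t2), b * np.sin(t3), b * np.cos(t3)], axis=1
    )


# -------------------------------------------------------------------- I/O

def write_quaternions(sampling: RotationSampling, path) -> None:
    """Plain-text quaternion file: header = count, then q0 q1 q2 q3 weight."""
    with open(path, "w") as fh:
        fh.write(f"{len(sampling)}\n")
        for (q0, q1, q2, q3), w in zip(sampling.quats, sampling.weights):
            fh.write(f"{q0:.12e} {q1:.12e} {q2:.12e} {q3:.12e} {w:.12e}\n")


def read_quaternions(path, level: int = 0) -> RotationSampling:
    with open(path) as fh:
        try:
            count = int(fh.readline().split()[0])
        except (ValueError, IndexError):
            raise FormatError("bad quaternion file header") from None
        data = np.loadtxt(fh, ndmin=2)
    if data.shape != (count, 5):
        raise FormatError(
            f"quaternion file promises {count} rows of 5 columns, got {data.shape}"
        )
    return RotationSampling(level=level, quats=data[:, :4], weights=data[:, 4])
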
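"""Sparse photon files: the six-block binary format, densify, powder.

Frames with few photons are stored sparsely: block 1 is a 1024-byte header
(two 32-bit integers — frame count and pixels per frame — then zero fill),
block 2 the per-frame count of one-photon pixels, block 3 the per-frame
count of multi-photon pixels, block 4 the pixel indices of the one-photon
events, block 5 the pixel indices of the multi-photon events and block 6
their photon counts.  All blocks hold native-endian 32-bit signed integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import FormatError

__all__ = ["SparsePhotonSet", "write_photons", "read_photons"]

HEADER_BYTES = 1024
_I32 = np.dtype(np.int32)


@dataclass
class SparsePhotonSet:
    """Sparse photon counts K_dt for a stack of diffraction frames."""

    num_pix: int
    ones: np.ndarray         # (num_data,) one-photon events per frame
    multi: np.ndarray        # (num_data,) multi-photon events per frame
    place_ones: np.ndarray   # (sum ones,) pixel indices
    place_multi: np.ndarray  # (sum multi,) pixel indices
    count_multi: np.ndarray  # (sum multi,) photon counts >= 2
    _o_off: np.ndarray = field(init=False, repr=False)
    _m_off: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name in ("ones", "multi", "place_ones", "place_multi", "count_multi"):
            setattr(self, name, np.ascontiguousarray(getattr(self, name), dtype=_I32))
        if len(self.ones) != len(self.multi):
            raise FormatError("ones and multi must have one entry per frame")
        if len(self.place_ones) != int(self.ones.sum()):
            raise FormatError("place_ones length != sum(ones)")
        if len(self.place_multi) != int(self.multi.sum()):
            raise FormatError("place_multi length != sum(multi)")
        if len(self.count_multi) != len(self.place_multi):
            raise FormatError("count_multi length != place_multi length")
        if np.any(self.ones < 0) or np.any(self.multi < 0):
            raise FormatError("negative event counts")
        for place in (self.place_ones, self.place_multi):
            if place.size and (place.min() < 0 or place.max() >= self.num_pix):
                raise FormatError("pixel index outside [0, num_pix)")
        if np.any(self.count_multi < 2):
            raise FormatError("count_multi entries must be >= 2")
        self._o_off = np.concatenate([[0], np.cumsum(self.ones)])
        self._m_off = np.concatenate([[0], np.cumsum(self.multi)])

    @property
    def num_data(self) -> int:
        return len(self.ones)

    @property
    def total_photons(self) -> int:
        return int(self.ones.sum()) + int(self.count_multi.sum())

    def frame_events(self, d: int):
        """(place_ones, place_multi, count_multi) slices of frame ``d``."""
        if not 0 <= d < self.num_data:
            raise IndexError(f"frame {d} outside [0, {self.num_data})")
        o0, o1 = self._o_off[d], self._o_off[d + 1]
        m0, m1 = self._m_off[d], self._m_off[d + 1]
        return (self.place_ones[o0:o1], self.place_multi[m0:m1],
                self.count_multi[m0:m1])

    def frame_to_dense(self, d: int) -> np.ndarray:
        """Per-pixel photon counts of frame ``d`` as a dense vector."""
        po, pm, cm = self.frame_events(d)
        dense = np.zeros(self.num_pix, dtype=np.int64)
        dense[po] = 1
        dense[pm] = cm
        return dense

    def powder_sum(self) -> np.ndarray:
        """Pixelwise sum over all frames (the virtual powder pattern)."""
        powder = np.bincount(self.place_ones, minlength=self.num_pix)
        powder = powder + np.bincount(
            self.place_multi, weights=self.count_multi.astype(np.float64),
            minlength=self.num_pix,
        ).astype(np.int64)
        return powder

    def to_csr(self, columns: np.ndarray | None = None):
        """Frames-by-pixels CSR matrix of photon counts.

        ``columns`` optionally restricts (and reorders) the pixel columns.
        """
        from scipy.sparse import csr_matrix

        indices = np.concatenate([self.place_ones, self.place_multi])
        data = np.concatenate([
            np.ones(len(self.place_ones)), self.count_multi.astype(np.float64),
        ])
        # rows: frame of each event, ones block first then multi block
        rows = np.concatenate([
            np.repeat(np.arange(self.num_data), self.ones),
            np.repeat(np.arange(self.num_data), self.multi),
        ])
        mat = csr_matrix(
            (data, (rows, indices)), shape=(self.num_data, self.num_pix)
        )
        if columns is not None:
            mat = mat[:, columns]
        return mat

    @classmethod
    def from_dense(cls, frames: np.ndarray, num_pix: int | None = None
                   ) -> "SparsePhotonSet":
        """Build a sparse set from a (num_data, num_pix) count array."""
        frames = np.asarray(frames)
        if frames.ndim != 2:
            raise ValueError("frames must be 2-D (num_data, num_pix)")
        if np.any(frames < 0):
            raise ValueError("negative photon counts")
        npx = num_pix if num_pix is not None else frames.shape[1]
        ones, multi, p_ones, p_multi, c_multi = [], [], [], [], []
        for row in frames:
            po = np.flatnonzero(row == 1)
            pm = np.flatnonzero(row >= 2)
            ones.append(len(po))
            multi.append(len(pm))
            p_ones.append(po)
            p_multi.append(pm)
            c_multi.append(row[pm])
        return cls(
            num_pix=npx,
            ones=np.asarray(ones), multi=np.asarray(multi),
            place_ones=np.concatenate(p_ones) if p_ones else np.empty(0, _I32),
            place_multi=np.concatenate(p_multi) if p_multi else np.empty(0, _I32),
            count_multi=np.concatenate(c_multi) if c_multi else np.empty(0, _I32),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SparsePhotonSet):
            return NotImplemented
        return (
            self.num_pix == other.num_pix
            and all(
                np.array_equal(getattr(self, f), getattr(other, f))
                for f in ("ones", "multi", "place_ones", "place_multi",
                          "count_multi")
            )
        )


def write_photons(ps: SparsePhotonSet, path) -> None:
    """Serialize to the six-block binary layout (native endianness)."""
    if ps.num_data >= 2 ** 31 or ps.num_pix >= 2 ** 31:
        raise FormatError("count overflows 32-bit header field")
    with open(path, "wb") as fh:
        header = np.zeros(HEADER_BYTES, dtype=np.uint8)
        header[:8] = np.frombuffer(
            np.asarray([ps.num_data, ps.num_pix], dtype=_I32).tobytes(),
            dtype=np.uint8,
        )
        fh.write(header.tobytes())
        for block in (ps.ones, ps.multi, ps.place_ones, ps.place_multi,
                      ps.count_multi):
            fh.write(np.ascontiguousarray(block, dtype=_I32).tobytes())


def read_photons(path) -> SparsePhotonSet:
    """Parse a six-block photon file; errors name the truncated block."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < HEADER_BYTES:
        raise FormatError(
            f"header truncated: file has {len(raw)} < {HEADER_BYTES} bytes"
        )
    num_data, num_pix = np.frombuffer(raw[:8], dtype=_I32)
    if num_data < 0 or num_pix < 0:
        raise FormatError("negative frame or pixel count in header")
    offset = HEADER_BYTES

    def take(count: int, block: str) -> np.ndarray:
        nonlocal offset
        nbytes = 4 * count
        if offset + nbytes > len(raw):
            raise FormatError(
                f"{block} block truncated: need {nbytes} bytes at offset "
                f"{offset}, file has {len(raw)}"
            )
        arr = np.frombuffer(raw, dtype=_I32, count=count, offset=offset)
        offset += nbytes
        return arr

    ones = take(int(num_data), "ones")
    multi = take(int(num_data), "multi")
    if np.any(ones < 0) or np.any(multi < 0):
        raise FormatError("negative event count in ones/multi block")
    place_ones = take(int(ones.sum()), "place_ones")
    place_multi = take(int(multi.sum()), "place_multi")
    count_multi = take(int(multi.sum()), "count_multi")
    if offset != len(raw):
        raise FormatError(
            f"{len(raw) - offset} trailing bytes after count_multi block"
        )
    return SparsePhotonSet(
        num_pix=int(num_pix), ones=ones, multi=multi, place_ones=place_ones,
        place_multi=place_multi, count_multi=count_multi,
    )
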
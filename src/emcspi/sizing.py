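"""Experiment-planning calculator.

Given the signal-to-noise parameter S, the mean photon count per frame N,
the speckle sampling sigma and the dimensionless particle radius
R_bar = R_p / a, the planner reports how large an experiment and a
reconstruction will be:

* rotation samples ``M_rot = 10 (5 n^3 + n)`` at refinement level
  ``n = round(R_bar)`` (the sampling criterion ties the angular step to
  the particle's dimensionless radius);
* required frames ``M_data = S^2 M_rot / N`` — S^2 is the average number
  of photons per orientation;
* conditional probabilities ``M_prob = M_data * M_rot`` (8-byte entries);
* dense cubic model of side ``2 sigma R_bar`` voxels (8 bytes each);
* sparse data entries ``M_sp <= N * M_data`` (8 bytes per index+count pair).

Memory figures use binary units (MB = 1024^2 bytes, GB = 1024^3 bytes).
"""

from __future__ import annotations

from dataclasses import dataclass

from .rotations import num_samples

__all__ = ["SizingReport", "sizing_report"]

_MB = 1024.0 ** 2
_GB = 1024.0 ** 3
_BYTES_PER_ENTRY = 8


@dataclass
class SizingReport:
    S: float
    N: float
    sigma: float
    R_bar: float
    n_level: int
    M_rot: int
    M_data: int
    M_tomo: float   # detector pixels, proportional to (sigma R_bar)^2
    M_sp_mb: float
    M_W_mb: float
    M_prob_gb: float

    def as_text(self) -> str:
        return "\n".join([
            f"S          = {self.S:g}",
            f"N          = {self.N:g}",
            f"sigma      = {self.sigma:g}",
            f"R_bar      = {self.R_bar:g}",
            f"n_level    = {self.n_level}",
            f"M_rot      = {self.M_rot}",
            f"M_data     = {self.M_data}",
            f"M_tomo     = {self.M_tomo:g}",
            f"M_sp_MB    = {self.M_sp_mb:.4g}",
            f"M_W_MB     = {self.M_W_mb:.4g}",
            f"M_prob_GB  = {self.M_prob_gb:.4g}",
        ])


def sizing_report(S: float, N: float, sigma: float, R_bar: float) -> SizingReport:
    """Compute the sizing table row for one (S, N, sigma, R_bar)."""
    if S <= 0 or N <= 0 or sigma <= 0 or R_bar <= 0:
        raise ValueError("all planner inputs must be > 0")
    n_level = max(1, int(round(R_bar)))
    m_rot = num_samples(n_level)
    m_data = int(round(S * S * m_rot / N))
    m_tomo = (sigma * R_bar) ** 2
    m_w_voxels = (2.0 * sigma * R_bar) ** 3
    return SizingReport(
        S=S, N=N, sigma=sigma, R_bar=R_bar, n_level=n_level,
        M_rot=m_rot, M_data=m_data, M_tomo=m_tomo,
        M_sp_mb=N * m_data * _BYTES_PER_ENTRY / _MB,
        M_W_mb=m_w_voxels * _BYTES_PER_ENTRY / _MB,
        M_prob_gb=m_data * m_rot * _BYTES_PER_ENTRY / _GB,
    )
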
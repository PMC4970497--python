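"""Experiment configuration: INI parsing and derived beamline geometry.

The configuration file is a plain-text INI dialect with ``#`` comments and a
mandatory ``[parameters]`` section holding the beamline parameters (detector
distance, wavelength, detector size, pixel size, beamstop radius,
polarization).  Reconstruction and simulation settings live in the
``[emc]``, ``[make_detector]`` and ``[make_data]`` sections.

From these parameters the half-period resolution, field of view and the
dimensionless particle radius follow; :func:`compute_geometry` evaluates
them in the crystallographic convention q = 2 sin(theta) / lambda, with the
resolution defined from the detector edge and the maximum scattering angle
from the detector corner.
"""

from __future__ import annotations

import configparser
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .exceptions import ConfigError

__all__ = ["ExperimentConfig", "GeometrySummary", "parse_config", "compute_geometry"]

#: keys that have no sensible default and must appear in [parameters]
REQUIRED_KEYS = ("detd", "lambda", "detsize", "pixsize")

_FLOAT_KEYS = {
    "detd", "lambda", "pixsize", "stoprad", "beta_start", "beta_jump",
    "mean_count", "fluence_spread_frac", "background_mean",
}
_INT_KEYS = {"detsize", "num_div", "beta_period", "num_data", "seed"}
_BOOL_KEYS = {"need_scaling"}
_STR_KEYS = {
    "polarization", "in_detector_file", "in_photons_file", "output_folder",
    "in_quat_file", "start_model_file",
}
_KNOWN = _FLOAT_KEYS | _INT_KEYS | _BOOL_KEYS | _STR_KEYS | {"beta_schedule"}


@dataclass
class ExperimentConfig:
    """Beamline, reconstruction and simulation parameters.

    Units: ``detd`` and ``pixsize`` in mm, ``wavelength`` in Angstrom,
    ``detsize`` and ``stoprad`` in pixels.
    """

    detd: float
    wavelength: float
    detsize: int
    pixsize: float
    stoprad: float = 0.0
    polarization: str = "x"
    # reconstruction
    num_div: int = 2
    beta_start: float = 1.0
    beta_jump: float = 1.0
    beta_period: int = 10
    need_scaling: bool = False
    seed: int = 0
    # simulation
    num_data: int = 1000
    mean_count: float = 100.0
    fluence_spread_frac: float = 0.0
    background_mean: float = 0.0
    # file paths
    in_detector_file: str = "detector.dat"
    in_photons_file: str = "photons.emc"
    in_quat_file: str = ""
    start_model_file: str = ""
    output_folder: str = "output"
    # unrecognized keys, preserved verbatim
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.detd <= 0:
            raise ConfigError("detd must be > 0")
        if self.wavelength <= 0:
            raise ConfigError("lambda must be > 0")
        if self.detsize < 2:
            raise ConfigError("detsize must be >= 2")
        if self.pixsize <= 0:
            raise ConfigError("pixsize must be > 0")
        if not 0 <= self.stoprad < self.detsize / 2 * math.sqrt(2):
            raise ConfigError("stoprad must lie in [0, detsize/2*sqrt(2))")
        if self.polarization not in ("x", "y", "none"):
            raise ConfigError("polarization must be one of x, y, none")
        if self.num_div < 1:
            raise ConfigError("num_div must be >= 1")
        if not 0 < self.beta_start <= 1:
            raise ConfigError("beta_start must be in (0, 1]")
        if self.beta_jump < 1:
            raise ConfigError("beta_jump must be >= 1")
        if self.beta_period < 1:
            raise ConfigError("beta_period must be >= 1")

    @property
    def detd_px(self) -> float:
        """Detector distance in pixel units."""
        return self.detd / self.pixsize


@dataclass
class GeometrySummary:
    """Derived experiment geometry.

    ``a`` is the half-period resolution from the detector edge (nm), ``L``
    the full field of view (nm), ``phi_max`` the scattering angle to the
    detector corner (rad).  When the particle radius ``R_p`` (nm) is known,
    ``R_bar = R_p / a`` is the dimensionless radius and
    ``sigma = L / (2 R_p)`` the speckle sampling.
    """

    phi_max: float
    phi_edge: float
    a: float
    L: float
    R_p: Optional[float] = None
    R_bar: Optional[float] = None
    sigma: Optional[float] = None


def _find_line(text: str, key: str) -> int:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if stripped.lower().startswith(key.lower()) and "=" in stripped:
            return lineno
    return -1


def parse_config(text: str) -> ExperimentConfig:
    """Parse configuration text into an :class:`ExperimentConfig`.

    All sections are scanned; keys may appear in whichever section their
    module uses.  Unknown keys are preserved in ``extra`` and produce a
    warning, not an error.  The special ``beta_schedule`` key takes two
    whitespace-separated numbers, ``beta_jump`` and ``beta_period``.
    """
    cp = configparser.ConfigParser(
        comment_prefixes=("#",), inline_comment_prefixes=("#",),
        interpolation=None,
    )
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"cannot parse configuration: {exc}") from exc
    if "parameters" not in cp:
        raise ConfigError("configuration is missing the [parameters] section")

    items: dict[str, str] = {}
    for section in cp.sections():
        for key, value in cp.items(section):
            items[key.strip().lower()] = value.strip()

    missing = [k for k in REQUIRED_KEYS if k not in items]
    if missing:
        raise ConfigError(
            "required [parameters] keys missing: " + ", ".join(missing)
        )

    kwargs: dict = {}
    extra: dict[str, str] = {}

    def numeric(key: str, conv, raw: str):
        try:
            return conv(float(raw)) if conv is int else conv(raw)
        except ValueError:
            line = _find_line(text, key)
            raise ConfigError(
                f"non-numeric value {raw!r} for key {key!r} (line {line})"
            ) from None

    for key, raw in items.items():
        if key == "lambda":
            kwargs["wavelength"] = numeric(key, float, raw)
        elif key == "beta_schedule":
            parts = raw.split()
            if len(parts) != 2:
                raise ConfigError(
                    "beta_schedule takes two whitespace-separated numbers"
                )
            kwargs["beta_jump"] = numeric("beta_schedule", float, parts[0])
            kwargs["beta_period"] = numeric("beta_schedule", int, parts[1])
        elif key in _FLOAT_KEYS:
            kwargs[key] = numeric(key, float, raw)
        elif key in _INT_KEYS:
            kwargs[key] = numeric(key, int, raw)
        elif key in _BOOL_KEYS:
            kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
        elif key in _STR_KEYS:
            kwargs[key] = raw
        else:
            extra[key] = raw

    if extra:
        warnings.warn(
            "unrecognized configuration keys: " + ", ".join(sorted(extra)),
            stacklevel=2,
        )
    return ExperimentConfig(extra=extra, **kwargs)


def compute_geometry(
    cfg: ExperimentConfig, R_p: Optional[float] = None
) -> GeometrySummary:
    """Derive resolution and field of view from the beamline parameters.

    Parameters
    ----------
    cfg
        Validated experiment configuration.
    R_p
        Optional particle radius in nm; enables ``R_bar`` and ``sigma``.
    """
    lam_nm = cfg.wavelength / 10.0  # Angstrom -> nm
    half = cfg.detsize / 2.0 * cfg.pixsize
    phi_edge = math.atan2(half, cfg.detd)
    phi_max = math.atan2(half * math.sqrt(2.0), cfg.detd)
    a = lam_nm / (4.0 * math.sin(phi_edge / 2.0))
    L = lam_nm * cfg.detd / cfg.pixsize
    summary = GeometrySummary(phi_max=phi_max, phi_edge=phi_edge, a=a, L=L)
    if R_p is not None:
        if R_p <= 0:
            raise ConfigError("particle radius must be > 0")
        summary.R_p = R_p
        summary.R_bar = R_p / a
        summary.sigma = L / (2.0 * R_p)
    return summary
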
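"""Units, physical constants and the camera calibration model.

The pipeline works in absolute photon radiance, photons s⁻¹ m⁻² sr⁻¹ nm⁻¹,
because photoreceptors count photons rather than integrate energy.  On top of
the linear unit sits the logarithmic "lit" scale,

    lit = log10(photon radiance),

under which natural light environments span a compact numeric range (starlight
≈ 9 lit, moonlight ≈ 11 lit, overcast ≈ 15–16 lit, direct sunlight ≈ 16–18
lit) and two decimal places resolve changes below the human contrast
threshold (0.01 lit ≈ 2.3% linear).

This module holds the unit conversions, the spectral-band definitions
(100-nm red/green/blue slots plus their white union), and the
:class:`CameraCalibration` data model that maps raw sensor counts to absolute
radiance: per-channel scale constants, black/white levels, ISO and aperture
gain tables, and a vignetting-versus-off-axis-angle table sampled every 10°.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

__all__ = [
    "PLANCK_CONSTANT",
    "SPEED_OF_LIGHT",
    "SATURATION_FRACTION",
    "SpectralBand",
    "BANDS",
    "CHANNELS",
    "ExposureMeta",
    "CameraCalibration",
    "to_lit",
    "from_lit",
    "lit_span_to_factor",
    "ev_to_factor",
    "photon_energy",
    "photon_energy_percent_diff",
    "energy_to_photon_radiance",
    "counts_to_radiance",
    "vignetting_correct",
    "white_from_rgb",
]

# CODATA 2018
PLANCK_CONSTANT = 6.62607015e-34  # J s (exact)
SPEED_OF_LIGHT = 299_792_458.0  # m s⁻¹ (exact)

#: Counts at or above this fraction of the white level are treated as saturated.
SATURATION_FRACTION = 0.99

#: Relative clamp applied to non-positive radiances after black-level
#: subtraction: floor = RADIANCE_FLOOR_FRACTION × smallest positive value.
RADIANCE_FLOOR_FRACTION = 1e-3


class SpectralBand(NamedTuple):
    """A contiguous wavelength slot, in nm."""

    name: str
    lambda_min: float
    lambda_max: float


#: The three 100-nm camera slots and their 300-nm union.
BANDS: dict[str, SpectralBand] = {
    "blue": SpectralBand("blue", 400.0, 500.0),
    "green": SpectralBand("green", 500.0, 600.0),
    "red": SpectralBand("red", 600.0, 700.0),
    "white": SpectralBand("white", 400.0, 700.0),
}

#: Channel order of the third image axis throughout the package.
CHANNELS = ("red", "green", "blue")


# ---------------------------------------------------------------------------
# log-unit arithmetic
# ---------------------------------------------------------------------------

def to_lit(radiance):
    """Convert linear photon radiance to the logarithmic lit scale.

    Parameters
    ----------
    radiance : array_like
        Photon radiance in photons s⁻¹ m⁻² sr⁻¹ nm⁻¹; must be finite and > 0
        (non-positive values are clamped upstream, see
        :func:`counts_to_radiance`).

    Returns
    -------
    ndarray or float
        log10 of the input.
    """
    arr = np.asarray(radiance, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite radiance: corrupt data reached to_lit()")
    if np.any(arr <= 0):
        raise ValueError(
            "non-positive radiance reached to_lit(); apply the radiance floor first"
        )
    out = np.log10(arr)
    return out if out.ndim else float(out)


def from_lit(lit):
    """Inverse of :func:`to_lit`: 10**lit."""
    arr = np.asarray(lit, dtype=float)
    out = np.power(10.0, arr)
    return out if out.ndim else float(out)


def lit_span_to_factor(span):
    """Linear factor (and percent change) equivalent to a lit interval.

    Returns ``(factor, percent)`` with ``factor = 10**span`` and
    ``percent = (factor - 1) * 100``.  A span of 0.01 lit is a 2.3% linear
    change; 2 lit is a factor of 100.
    """
    span = float(span)
    if not np.isfinite(span):
        raise ValueError("span must be finite")
    factor = 10.0 ** span
    return factor, (factor - 1.0) * 100.0


def ev_to_factor(delta_ev):
    """Linear exposure factor for an EV offset (1 EV = a factor of 2)."""
    delta_ev = np.asarray(delta_ev, dtype=float)
    if not np.all(np.isfinite(delta_ev)):
        raise ValueError("EV offset must be finite")
    out = np.power(2.0, delta_ev)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# photon arithmetic
# ---------------------------------------------------------------------------

def photon_energy(lambda_nm):
    """Energy of one photon at wavelength ``lambda_nm``, in joules (hc/λ)."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = PLANCK_CONSTANT * SPEED_OF_LIGHT / (lam * 1e-9)
    return out if out.ndim else float(out)


def photon_energy_percent_diff(lambda1_nm, lambda2_nm):
    """Percent difference in photon energy between two wavelengths.

    Returns ``(E(λ1)/E(λ2) − 1) × 100``.  Across the visible spectrum,
    400 nm versus 700 nm, the difference is 75%.
    """
    return (photon_energy(lambda1_nm) / photon_energy(lambda2_nm) - 1.0) * 100.0


def energy_to_photon_radiance(radiance_w, lambda_nm):
    """Convert energy radiance (W m⁻² sr⁻¹ nm⁻¹) to photon radiance.

    Divides by the per-photon energy: ``L_photon = L_e · λ / (hc)``.
    """
    le = np.asarray(radiance_w, dtype=float)
    if np.any(le < 0):
        raise ValueError("energy radiance must be non-negative")
    out = le / photon_energy(lambda_nm)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# exposure metadata and calibration model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureMeta:
    """Exposure settings of a single frame.

    ``ev_offset`` is the frame's position within a bracketing set, in EV
    (factor-2) steps relative to the base exposure.
    """

    exposure_time: float  # seconds
    iso: float
    f_number: float
    ev_offset: float = 0.0

    def __post_init__(self):
        if not (self.exposure_time > 0 and self.iso > 0 and self.f_number > 0):
            raise ValueError(
                "exposure_time, iso and f_number must all be positive, got "
                f"t={self.exposure_time}, ISO={self.iso}, N={self.f_number}"
            )

    def to_dict(self) -> dict:
        return {
            "exposure_time": self.exposure_time,
            "iso": self.iso,
            "f_number": self.f_number,
            "ev_offset": self.ev_offset,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExposureMeta":
        missing = [k for k in ("exposure_time", "iso", "f_number") if k not in d]
        if missing:
            raise KeyError(f"exposure metadata missing required field(s): {missing}")
        return cls(
            exposure_time=float(d["exposure_time"]),
            iso=float(d["iso"]),
            f_number=float(d["f_number"]),
            ev_offset=float(d.get("ev_offset", 0.0)),
        )


#: Off-axis angles (degrees) at which vignetting tables are sampled.
VIGNETTING_THETA_GRID = np.arange(0.0, 91.0, 10.0)


def _nearest_key(table: Mapping[float, object], key: float, what: str):
    """Exact-match lookup with nearest-key fallback (with a warning)."""
    keys = np.array(sorted(table))
    if key in table:
        return table[key]
    nearest = float(keys[np.argmin(np.abs(keys - key))])
    warnings.warn(
        f"{what} {key} not in calibration table; using nearest calibrated "
        f"value {nearest}",
        stacklevel=3,
    )
    return table[nearest]


@dataclass
class CameraCalibration:
    """Everything needed to turn sensor counts into absolute photon radiance.

    Attributes
    ----------
    channel_scale
        Per-channel constants K_ch (counts → photons s⁻¹ m⁻² sr⁻¹ nm⁻¹ at the
        reference exposure time, ISO and aperture), keyed ``red/green/blue``.
    black_level, white_level
        Sensor offset and clipping point, in counts.
    iso_gain, aperture_gain
        Relative linear gain versus ISO setting and relative transmission
        versus f-number; exact-match lookup with nearest-key fallback.
    vignetting
        Per-aperture relative transmission V(θ) sampled at 10° steps of
        off-axis angle θ from 0° to 90°; V(0°) = 1 by construction.
    projection
        Fisheye geometry: ``model`` (only ``"equisolid"``), ``center_xy``,
        ``radius_px`` and the raster ``image_size`` (height, width).
    """

    channel_scale: dict[str, float]
    black_level: float
    white_level: float
    iso_gain: dict[float, float]
    aperture_gain: dict[float, float]
    vignetting: dict[float, np.ndarray]
    projection: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vignetting = {
            float(k): np.asarray(v, dtype=float) for k, v in self.vignetting.items()
        }
        self.iso_gain = {float(k): float(v) for k, v in self.iso_gain.items()}
        self.aperture_gain = {
            float(k): float(v) for k, v in self.aperture_gain.items()
        }
        self.validate()

    def validate(self) -> None:
        missing = [ch for ch in CHANNELS if ch not in self.channel_scale]
        if missing:
            raise ValueError(f"calibration missing channel scale(s): {missing}")
        if not self.black_level < self.white_level:
            raise ValueError(
                f"black_level ({self.black_level}) must be below white_level "
                f"({self.white_level})"
            )
        for ap, table in self.vignetting.items():
            if table.shape != VIGNETTING_THETA_GRID.shape:
                raise ValueError(
                    f"vignetting table for f/{ap} must have "
                    f"{VIGNETTING_THETA_GRID.size} entries (0°–90° by 10°)"
                )
            if not np.isclose(table[0], 1.0):
                raise ValueError(f"vignetting table for f/{ap} must have V(0°)=1")
            if np.any(table <= 0) or np.any(table > 1.0 + 1e-9):
                raise ValueError(f"vignetting for f/{ap} must satisfy 0 < V ≤ 1")

    # -- lookups ----------------------------------------------------------
    def scale_vector(self) -> np.ndarray:
        """K_ch as a length-3 vector in ``CHANNELS`` order."""
        return np.array([self.channel_scale[ch] for ch in CHANNELS])

    def iso_gain_for(self, iso: float) -> float:
        return float(_nearest_key(self.iso_gain, float(iso), "ISO"))

    def aperture_gain_for(self, f_number: float) -> float:
        return float(_nearest_key(self.aperture_gain, float(f_number), "f-number"))

    def vignetting_for(self, f_number: float) -> np.ndarray:
        return np.asarray(
            _nearest_key(self.vignetting, float(f_number), "vignetting aperture")
        )

    @property
    def saturation_threshold(self) -> float:
        return SATURATION_FRACTION * self.white_level

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "channels": dict(self.channel_scale),
            "black_level": self.black_level,
            "white_level": self.white_level,
            "iso_gain": {str(k): v for k, v in self.iso_gain.items()},
            "aperture_gain": {str(k): v for k, v in self.aperture_gain.items()},
            "vignetting": {
                str(k): list(map(float, v)) for k, v in self.vignetting.items()
            },
            "projection": self.projection,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CameraCalibration":
        required = (
            "channels",
            "black_level",
            "white_level",
            "iso_gain",
            "aperture_gain",
            "vignetting",
            "projection",
        )
        missing = [k for k in required if k not in d]
        if missing:
            raise KeyError(f"calibration file missing required key(s): {missing}")
        return cls(
            channel_scale={k: float(v) for k, v in d["channels"].items()},
            black_level=float(d["black_level"]),
            white_level=float(d["white_level"]),
            iso_gain={float(k): float(v) for k, v in d["iso_gain"].items()},
            aperture_gain={float(k): float(v) for k, v in d["aperture_gain"].items()},
            vignetting={float(k): v for k, v in d["vignetting"].items()},
            projection=dict(d["projection"]),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CameraCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# counts → radiance
# ---------------------------------------------------------------------------

def counts_to_radiance(
    counts: np.ndarray, meta: ExposureMeta, cal: CameraCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw sensor counts to linear photon radiance.

    The sensor model is linear after offset removal:

        L = (counts − black_level) · K_ch / (t · g_iso(S) · g_ap(N))

    Values at or below the black level are clamped to a small positive floor
    (1e-3 × the smallest positive radiance in the frame) so the logarithmic
    statistics stay finite; dark noise below the offset carries no usable
    radiance information anyway.

    Parameters
    ----------
    counts
        H×W×3 raw counts in ``CHANNELS`` (red, green, blue) order.
    meta, cal
        Exposure settings and the camera calibration.

    Returns
    -------
    radiance : ndarray
        H×W×3 photon radiance.
    saturated : ndarray of bool
        H×W×3 mask, True where counts reached the saturation threshold
        (``SATURATION_FRACTION × white_level``) and the radiance is only a
        lower bound.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3 or counts.shape[2] != len(CHANNELS):
        raise ValueError("counts must be an H×W×3 array (red, green, blue)")
    saturated = counts >= cal.saturation_threshold
    gain = (
        meta.exposure_time
        * cal.iso_gain_for(meta.iso)
        * cal.aperture_gain_for(meta.f_number)
    )
    radiance = (counts - cal.black_level) * (cal.scale_vector() / gain)
    positive = radiance[radiance > 0]
    floor = (
        RADIANCE_FLOOR_FRACTION * positive.min() if positive.size else np.finfo(float).tiny
    )
    return np.maximum(radiance, floor), saturated


def vignetting_correct(
    radiance: np.ndarray,
    theta_deg: np.ndarray,
    cal: CameraCalibration,
    f_number: float,
) -> np.ndarray:
    """Undo the lens's off-axis transmission fall-off.

    Each pixel is divided by V(θ), linearly interpolated from the calibrated
    10°-step table for the requested aperture.  ``theta_deg`` is the per-pixel
    off-axis angle; entries may be NaN outside the image circle (left
    untouched).
    """
    theta = np.asarray(theta_deg, dtype=float)
    finite = np.isfinite(theta)
    if np.any((theta[finite] < 0) | (theta[finite] > 90.0 + 1e-9)):
        raise ValueError("off-axis angle outside [0°, 90°]: geometry is broken")
    table = cal.vignetting_for(f_number)
    v = np.interp(np.where(finite, theta, 0.0), VIGNETTING_THETA_GRID, table)
    v = np.where(finite, v, 1.0)
    if radiance.ndim == theta.ndim + 1:
        v = v[..., None]
    return radiance / v


def white_from_rgb(red, green=None, blue=None):
    """Per-nm white radiance over 400–700 nm from the three 100-nm slots.

    Each colour slot spans 100 nm, so the per-nm average over the 300-nm
    union is simply (R + G + B) / 3.  Accepts either three arrays or a single
    ...×3 array in ``CHANNELS`` order.
    """
    if green is None:
        rgb = np.asarray(red, dtype=float)
        return (rgb[..., 0] + rgb[..., 1] + rgb[..., 2]) / 3.0
    return (
        np.asarray(red, dtype=float)
        + np.asarray(green, dtype=float)
        + np.asarray(blue, dtype=float)
    ) / 3.0
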
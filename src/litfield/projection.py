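"""Fisheye geometry and remapping to an elevation × azimuth raster.

The camera points at the horizon with a 180° circular fisheye whose radial
law is equisolid, r = 2f·sin(θ/2): normalizing by the 90° image-circle
radius gives r/R = sin(θ/2)/sin(45°).  The image circle therefore covers
every direction in the front hemisphere — elevation ε from −90° (straight
down) to +90° (straight up), azimuth φ from −90° to +90° about the optical
axis — with the horizontal plane running through the centre row.

``remap_to_equirect`` resamples the circular image onto a square
equirectangular raster (rows of constant elevation, columns of constant
azimuth, row 0 at the zenith) by inverse-mapped nearest-neighbour lookup:
each output cell centre is projected back into the fisheye image and copies
the nearest source pixel, so no new pixel values are ever invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .radiometry import ExposureMeta

__all__ = [
    "Direction",
    "FisheyeExposure",
    "EquirectImage",
    "radius_to_theta",
    "theta_to_radius",
    "image_point_to_direction",
    "direction_to_image_point",
    "theta_map",
    "bin_edges",
    "bin_centers",
    "row_elevations",
    "col_azimuths",
    "remap_to_equirect",
]

_SIN45 = np.sin(np.pi / 4.0)


class Direction(NamedTuple):
    """A viewing direction: elevation and azimuth in degrees.

    Elevation +90° is straight up, −90° straight down; azimuth is measured
    about the (horizontal) optical axis, positive to the right.
    """

    elevation: float
    azimuth: float


@dataclass
class FisheyeExposure:
    """A single circular fisheye frame plus its exposure metadata.

    ``pixels`` may hold raw counts (straight off the sensor) or linear
    radiance (after calibration); the geometry fields locate the 180° image
    circle inside the raster.
    """

    pixels: np.ndarray  # H×W×3
    meta: ExposureMeta
    center: tuple[float, float]  # (cx, cy) in pixel coordinates
    radius_px: float
    model: str = "equisolid"
    saturated: Optional[np.ndarray] = None  # H×W×3 bool

    def __post_init__(self):
        if self.model != "equisolid":
            raise NotImplementedError(
                f"projection model {self.model!r}; only 'equisolid' is implemented"
            )
        if self.radius_px <= 0:
            raise ValueError("image-circle radius must be positive")
        h, w = self.pixels.shape[:2]
        cx, cy = self.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("image-circle centre lies outside the raster")


@dataclass
class EquirectImage:
    """Square elevation × azimuth raster, the pipeline's working format.

    Row 0 is the zenith (ε = +90°), the last row the nadir; column 0 is
    azimuth −90°, the last +90°.  ``valid`` marks cells whose direction was
    covered by the source image; ``saturated`` carries the per-channel
    saturation mask through the pipeline.
    """

    pixels: np.ndarray  # M×M×3
    valid: np.ndarray  # M×M bool
    saturated: Optional[np.ndarray] = None  # M×M×3 bool

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("equirectangular image must be square (M×M×bands)")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def elevations(self) -> np.ndarray:
        return row_elevations(self.size)

    @property
    def azimuths(self) -> np.ndarray:
        return col_azimuths(self.size)


# ---------------------------------------------------------------------------
# the equisolid radial law
# ---------------------------------------------------------------------------

def radius_to_theta(r_norm):
    """Off-axis angle θ (degrees) from normalized radial distance r/R.

    Inverts the equisolid law: θ = 2·asin(r_norm · sin 45°).  The image rim
    (r_norm = 1) maps to θ = 90°.  Values outside [0, 1] return NaN (they lie
    outside the image circle).
    """
    r = np.asarray(r_norm, dtype=float)
    with np.errstate(invalid="ignore"):
        theta = np.degrees(2.0 * np.arcsin(np.where((r >= 0) & (r <= 1), r, np.nan) * _SIN45))
    return theta if theta.ndim else float(theta)


def theta_to_radius(theta_deg):
    """Normalized radial distance r/R for off-axis angle θ (degrees)."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    r = np.sin(t / 2.0) / _SIN45
    return r if r.ndim else float(r)


# ---------------------------------------------------------------------------
# direction ↔ image point
# ---------------------------------------------------------------------------
#
# With the optical axis horizontal, a pixel at normalized radius r and
# position angle ψ (measured from image-up, clockwise towards image-right)
# views the direction
#     d = cosθ·axis + sinθ·(cosψ·up + sinψ·right),
# so   ε = asin(sinθ·cosψ),   φ = atan2(d_right, d_axis).

def _point_to_direction_arrays(x, y, center, radius_px):
    dx = np.asarray(x, dtype=float) - center[0]
    dy = np.asarray(y, dtype=float) - center[1]
    r_norm = np.hypot(dx, dy) / radius_px
    theta = np.radians(radius_to_theta(r_norm))
    psi = np.arctan2(dx, -dy)  # image up is −y
    sin_t = np.sin(theta)
    elev = np.degrees(np.arcsin(np.clip(sin_t * np.cos(psi), -1.0, 1.0)))
    azim = np.degrees(np.arctan2(sin_t * np.sin(psi), np.cos(theta)))
    return elev, azim, r_norm


def image_point_to_direction(x, y, exposure: FisheyeExposure) -> Direction:
    """Viewing direction of an image point; raises if outside the circle."""
    elev, azim, r_norm = _point_to_direction_arrays(
        x, y, exposure.center, exposure.radius_px
    )
    if r_norm > 1.0:
        raise ValueError(f"point ({x}, {y}) lies outside the image circle")
    return Direction(float(elev), float(azim))


def direction_to_image_point(elevation, azimuth, center, radius_px):
    """Fisheye pixel coordinates viewing (ε, φ); the inverse of the above."""
    e = np.radians(np.asarray(elevation, dtype=float))
    a = np.radians(np.asarray(azimuth, dtype=float))
    d_axis = np.cos(e) * np.cos(a)
    d_right = np.cos(e) * np.sin(a)
    d_up = np.sin(e)
    theta = np.degrees(np.arccos(np.clip(d_axis, -1.0, 1.0)))
    psi = np.arctan2(d_right, d_up)
    r = radius_px * theta_to_radius(theta)
    return center[0] + r * np.sin(psi), center[1] - r * np.cos(psi)


def theta_map(exposure: FisheyeExposure) -> np.ndarray:
    """Per-pixel off-axis angle θ (degrees); NaN outside the image circle."""
    h, w = exposure.pixels.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    r_norm = (
        np.hypot(xx - exposure.center[0], yy - exposure.center[1])
        / exposure.radius_px
    )
    return radius_to_theta(r_norm)


# ---------------------------------------------------------------------------
# equirectangular grid conventions
# ---------------------------------------------------------------------------

def bin_edges(m: int) -> np.ndarray:
    """Row/cell edges in elevation for an M-row raster: +90 … −90."""
    return 90.0 - 180.0 * np.arange(m + 1) / m


def bin_centers(m: int) -> np.ndarray:
    return 90.0 - 180.0 * (np.arange(m) + 0.5) / m


def row_elevations(m: int) -> np.ndarray:
    """Elevation of each row centre, +90 → −90 from top to bottom."""
    return bin_centers(m)


def col_azimuths(m: int) -> np.ndarray:
    """Azimuth of each column centre, −90 → +90 left to right."""
    return -90.0 + 180.0 * (np.arange(m) + 0.5) / m


# ---------------------------------------------------------------------------
# the remap
# ---------------------------------------------------------------------------

def remap_to_equirect(
    exposure: FisheyeExposure, out_size: Optional[int] = None
) -> EquirectImage:
    """Resample a fisheye frame onto the square elevation × azimuth raster.

    Inverse-mapped nearest neighbour: each output cell centre (ε, φ) is
    projected to its real-valued fisheye preimage and copies the nearest
    source pixel.  Deterministic, hole-free, and value-preserving — the
    output is a multiset drawn from the input pixels.

    ``out_size`` defaults to the image-circle diameter (2·R_px), which
    preserves the sampling density along the equator.
    """
    if exposure.radius_px <= 0:
        raise ValueError("degenerate geometry: radius_px must be positive")
    m = int(out_size) if out_size else int(round(2 * exposure.radius_px))
    if m < 2:
        raise ValueError("output raster must be at least 2×2")

    elev = row_elevations(m)[:, None]
    azim = col_azimuths(m)[None, :]
    x, y = direction_to_image_point(elev, azim, exposure.center, exposure.radius_px)

    h, w = exposure.pixels.shape[:2]
    r_norm = (
        np.hypot(x - exposure.center[0], y - exposure.center[1]) / exposure.radius_px
    )
    # keep rim samples a pixel inside the circle so rounding (worst case
    # sqrt(2)/2 px diagonally) can never select a pixel outside the imaged
    # hemisphere
    r_max = 1.0 - 1.0 / exposure.radius_px
    shrink = np.where(r_norm > r_max, r_max / np.maximum(r_norm, 1e-12), 1.0)
    xi = np.rint(exposure.center[0] + (x - exposure.center[0]) * shrink).astype(np.intp)
    yi = np.rint(exposure.center[1] + (y - exposure.center[1]) * shrink).astype(np.intp)
    valid = (r_norm <= 1.0 + 1e-9) & (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    xi = np.clip(xi, 0, w - 1)
    yi = np.clip(yi, 0, h - 1)

    pixels = exposure.pixels[yi, xi]
    saturated = (
        exposure.saturated[yi, xi] if exposure.saturated is not None else None
    )
    return EquirectImage(pixels=pixels, valid=valid, saturated=saturated)
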
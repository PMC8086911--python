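"""Synthetic light environments and a forward camera model.

The generator builds ground-truth radiance fields with the three features
that dominate real light environments — an elevation-dependent radiance
profile per spectral band, azimuthal variation around each elevation, and
optional concentrated light sources — and then renders them through the
calibrated camera model (equisolid projection, vignetting, exposure scaling,
black level, clipping, quantization) into bracketed fisheye exposures.
Running the analysis pipeline on a rendered bracket and comparing with the
analytic truth is how the whole method is validated without field data.

The model per band is

    radiance(ε, φ) = 10^{ profile_band(ε) + σ(ε)·g(ε, φ) } ,

with ``profile`` a piecewise-linear lit-versus-elevation curve, ``g`` a
standard-normal texture field and σ the azimuthal spread in lit units — a
multiplicative log-normal, so a bin's analytic 95% contrast-span is simply
2·1.96·σ lit and its median is the profile itself.  The texture is shared
across bands by default (scene structure rather than chromatic noise), which
keeps the white channel's analytic truth exact; set ``chromatic_noise`` for
independent per-band fields.  Preset scenes are anchored to typical absolute
levels: sunlit ≈ 16–18 lit, overcast ≈ 15–16, indoor ≈ 14–15, moonlight ≈ 11,
starlight ≈ 9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .projection import (
    EquirectImage,
    FisheyeExposure,
    _point_to_direction_arrays,
    radius_to_theta,
    row_elevations,
    col_azimuths,
)
from .radiometry import (
    VIGNETTING_THETA_GRID,
    CameraCalibration,
    ExposureMeta,
    white_from_rgb,
)
from .stats import bin_index, stats_bin_centers, N_BINS

__all__ = [
    "LightSource",
    "SynthSceneSpec",
    "PRESETS",
    "make_truth",
    "truth_table",
    "synthetic_calibration",
    "render_bracket",
]

_BAND_AXIS = ("red", "green", "blue")


@dataclass(frozen=True)
class LightSource:
    """A small disk source: direction, angular radius and radiance (lit)."""

    elevation: float
    azimuth: float
    radius_deg: float
    lit: float


@dataclass
class SynthSceneSpec:
    """Ground-truth description a synthetic scene is rendered from.

    ``profiles`` maps each colour band to piecewise-linear (elevation, lit)
    knots; ``sigma`` is either a scalar or its own knot list, in lit units.
    Everything is reproducible from ``seed``.
    """

    profiles: dict[str, list[tuple[float, float]]]
    sigma: float | list[tuple[float, float]] = 0.2
    sources: list[LightSource] = field(default_factory=list)
    name: str = "custom"
    seed: int = 0
    chromatic_noise: bool = False

    def __post_init__(self):
        missing = [b for b in _BAND_AXIS if b not in self.profiles]
        if missing:
            raise ValueError(f"profiles missing band(s): {missing}")
        if self.sigma_at(np.array([0.0]))[0] < 0:
            raise ValueError("sigma must be non-negative")

    def profile_lit(self, band: str, elevation) -> np.ndarray:
        knots = sorted(self.profiles[band])
        e = np.array([k[0] for k in knots])
        v = np.array([k[1] for k in knots])
        return np.interp(np.asarray(elevation, dtype=float), e, v)

    def sigma_at(self, elevation) -> np.ndarray:
        e_arr = np.asarray(elevation, dtype=float)
        if np.isscalar(self.sigma) or isinstance(self.sigma, (int, float)):
            return np.full_like(e_arr, float(self.sigma))
        knots = sorted(self.sigma)
        e = np.array([k[0] for k in knots])
        v = np.array([k[1] for k in knots])
        return np.interp(e_arr, e, v)

    def shifted(self, delta_lit: float) -> "SynthSceneSpec":
        """The same scene, uniformly brighter/dimmer by ``delta_lit``."""
        profiles = {
            b: [(e, v + delta_lit) for e, v in knots]
            for b, knots in self.profiles.items()
        }
        sources = [replace(s, lit=s.lit + delta_lit) for s in self.sources]
        return replace(self, profiles=profiles, sources=sources)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "profiles": {b: [list(k) for k in v] for b, v in self.profiles.items()},
            "sigma": self.sigma
            if np.isscalar(self.sigma)
            else [list(k) for k in self.sigma],
            "sources": [
                [s.elevation, s.azimuth, s.radius_deg, s.lit] for s in self.sources
            ],
            "name": self.name,
            "seed": self.seed,
            "chromatic_noise": self.chromatic_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSceneSpec":
        sigma = d.get("sigma", 0.2)
        if isinstance(sigma, list):
            sigma = [tuple(k) for k in sigma]
        return cls(
            profiles={
                b: [tuple(k) for k in v] for b, v in d["profiles"].items()
            },
            sigma=sigma,
            sources=[LightSource(*s) for s in d.get("sources", [])],
            name=d.get("name", "custom"),
            seed=int(d.get("seed", 0)),
            chromatic_noise=bool(d.get("chromatic_noise", False)),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "SynthSceneSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SynthSceneSpec":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        spec = SynthSceneSpec.from_dict(PRESETS[name])
        return replace(spec, name=name, seed=seed)


def _flat(lit: float) -> list[tuple[float, float]]:
    return [(-90.0, lit), (90.0, lit)]


def _sky_ground(ground: float, sky: float) -> list[list[float]]:
    """Flat ground, flat sky, linear transition across the horizon band."""
    return [[-90.0, ground], [-5.0, ground], [5.0, sky], [90.0, sky]]


#: Preset scenes anchored to typical absolute radiance regimes (lit).
PRESETS: dict[str, dict] = {
    "sunlit": {
        "name": "sunlit",
        "profiles": {
            "red": _sky_ground(16.55, 16.25),
            "green": _sky_ground(16.60, 16.65),
            "blue": _sky_ground(16.15, 17.05),
        },
        "sigma": [[-90.0, 0.35], [-5.0, 0.30], [10.0, 0.12], [90.0, 0.08]],
    },
    "overcast": {
        "name": "overcast",
        "profiles": {
            "red": _sky_ground(15.15, 15.55),
            "green": _sky_ground(15.25, 15.75),
            "blue": _sky_ground(15.05, 15.80),
        },
        "sigma": [[-90.0, 0.18], [-5.0, 0.15], [10.0, 0.05], [90.0, 0.04]],
    },
    "indoor": {
        "name": "indoor",
        "profiles": {
            "red": _sky_ground(14.35, 14.75),
            "green": _sky_ground(14.25, 14.55),
            "blue": _sky_ground(13.95, 14.25),
        },
        "sigma": 0.35,
    },
    "moonlight": {
        "name": "moonlight",
        "profiles": {
            "red": _sky_ground(10.90, 11.15),
            "green": _sky_ground(10.85, 11.15),
            "blue": _sky_ground(10.70, 11.10),
        },
        "sigma": [[-90.0, 0.35], [-5.0, 0.30], [10.0, 0.12], [90.0, 0.08]],
    },
    "starlight": {
        "name": "starlight",
        "profiles": {
            "red": _sky_ground(8.90, 9.10),
            "green": _sky_ground(8.85, 9.05),
            "blue": _sky_ground(8.75, 9.00),
        },
        "sigma": 0.25,
    },
}


# ---------------------------------------------------------------------------
# truth field
# ---------------------------------------------------------------------------

def make_truth(spec: SynthSceneSpec, size: int = 512) -> EquirectImage:
    """Render the analytic scene onto an equirectangular radiance raster."""
    elev = row_elevations(size)
    azim = col_azimuths(size)
    rng = np.random.default_rng(spec.seed)
    sigma = spec.sigma_at(elev)[:, None]

    if spec.chromatic_noise:
        textures = [rng.standard_normal((size, size)) for _ in _BAND_AXIS]
    else:
        textures = [rng.standard_normal((size, size))] * len(_BAND_AXIS)

    pixels = np.empty((size, size, 3))
    for k, band in enumerate(_BAND_AXIS):
        lit = spec.profile_lit(band, elev)[:, None] + sigma * textures[k]
        pixels[..., k] = 10.0 ** lit

    if spec.sources:
        e = np.radians(elev)[:, None]
        a = np.radians(azim)[None, :]
        d = np.stack(
            [np.cos(e) * np.cos(a), np.cos(e) * np.sin(a), np.sin(e) * np.ones_like(a)],
            axis=-1,
        )
        for src in spec.sources:
            se, sa = np.radians(src.elevation), np.radians(src.azimuth)
            sd = np.array(
                [np.cos(se) * np.cos(sa), np.cos(se) * np.sin(sa), np.sin(se)]
            )
            inside = d @ sd >= np.cos(np.radians(src.radius_deg))
            pixels[inside] = 10.0 ** src.lit

    return EquirectImage(pixels=pixels, valid=np.ones((size, size), dtype=bool))


def truth_table(
    spec: SynthSceneSpec, size: int = 512, n_bins: int = N_BINS
) -> pd.DataFrame:
    """Analytic per-bin medians and 95% spans the pipeline should recover.

    The bin median in lit is the profile averaged over the bin's row centres
    (exact for linear segments under the symmetric texture); the 95% span is
    2·1.96·σ at the bin centre, neglecting the small within-bin profile
    spread.  Bins touched by a disk source are flagged ``has_source``; their
    analytic values ignore the source and are not expected to be recovered.
    """
    elev = row_elevations(size)
    rows = bin_index(elev, n_bins)
    centers = stats_bin_centers(n_bins)

    out = {"elevation": centers}
    band_profiles = {
        b: spec.profile_lit(b, elev) for b in _BAND_AXIS
    }
    band_profiles["white"] = np.log10(
        np.mean([10.0 ** band_profiles[b] for b in _BAND_AXIS], axis=0)
    )
    for band in ("white", *_BAND_AXIS):
        out[f"{band}_median_lit"] = np.array(
            [band_profiles[band][rows == b].mean() for b in range(n_bins)]
        )
    out["span95_lit"] = 2.0 * 1.96 * spec.sigma_at(centers)

    flagged = np.zeros(n_bins, dtype=bool)
    for src in spec.sources:
        reach = src.radius_deg + 180.0 / size
        flagged |= np.abs(centers - src.elevation) <= reach + 180.0 / n_bins
    out["has_source"] = flagged
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# the forward camera model
# ---------------------------------------------------------------------------

def synthetic_calibration(
    radius_px: int = 256,
    black_level: float = 256.0,
    white_level: float = 15871.0,
    vignetting_strength: float = 0.3,
) -> CameraCalibration:
    """A synthetic but realistic camera calibration for simulation and tests.

    Per-channel scale constants differ (as real sensor sensitivities do), the
    ISO gain table is linear in ISO, and the vignetting table falls off
    smoothly to ``1 − vignetting_strength`` at the 90° rim.
    """
    theta = np.radians(VIGNETTING_THETA_GRID)
    v = 1.0 - vignetting_strength * np.sin(theta) ** 2
    size = int(2 * radius_px + 8)
    return CameraCalibration(
        channel_scale={"red": 1.1e12, "green": 1.0e12, "blue": 1.35e12},
        black_level=black_level,
        white_level=white_level,
        iso_gain={iso: iso / 100.0 for iso in (100, 200, 400, 800, 1600)},
        aperture_gain={3.5: 1.0, 8.0: 0.191, 22.0: 0.0253},
        vignetting={3.5: v, 8.0: v, 22.0: v},
        projection={
            "model": "equisolid",
            "center_xy": [(size - 1) / 2.0, (size - 1) / 2.0],
            "radius_px": float(radius_px),
            "image_size": [size, size],
        },
    )


def _auto_exposure_time(truth: EquirectImage, cal: CameraCalibration,
                        meta: ExposureMeta, target_fraction: float = 0.05) -> float:
    """Exposure time putting the median green count at a fraction of white."""
    median_green = float(np.median(truth.pixels[truth.valid][:, 1]))
    gain = cal.iso_gain_for(meta.iso) * cal.aperture_gain_for(meta.f_number)
    target = target_fraction * (cal.white_level - cal.black_level)
    return target * cal.channel_scale["green"] / (median_green * gain)


def render_bracket(
    truth: EquirectImage,
    cal: CameraCalibration,
    ev_offsets: Sequence[float] = (-3.0, 0.0, 3.0),
    base_meta: Optional[ExposureMeta] = None,
    quantize: bool = True,
) -> list[FisheyeExposure]:
    """Render a truth field into a bracketed set of raw fisheye exposures.

    The inverse of the analysis chain: forward-map each fisheye pixel's
    viewing direction to its nearest equirectangular truth cell, apply
    vignetting, scale by the exposure (time × ISO gain × aperture
    transmission / channel scale), add the black level, clip at the white
    level and (optionally) quantize to whole counts.  Saturation therefore
    occurs exactly where truth × exposure reaches the white level.

    If ``base_meta`` is omitted, the EV-0 exposure time is chosen so the
    scene's median lands at 5% of the white level, leaving the ±3 EV frames
    comfortably inside the sensor's range.
    """
    proj = cal.projection
    h, w = proj["image_size"]
    center = tuple(proj["center_xy"])
    radius = float(proj["radius_px"])
    m = truth.size

    if base_meta is None:
        base_meta = ExposureMeta(exposure_time=1.0, iso=100.0, f_number=3.5)
        base_meta = ExposureMeta(
            exposure_time=_auto_exposure_time(truth, cal, base_meta),
            iso=base_meta.iso,
            f_number=base_meta.f_number,
        )

    yy, xx = np.mgrid[0:h, 0:w]
    elev, azim, r_norm = _point_to_direction_arrays(xx, yy, center, radius)
    inside = r_norm <= 1.0
    i = np.clip(np.nan_to_num((90.0 - elev) / 180.0 * m).astype(int), 0, m - 1)
    j = np.clip(np.nan_to_num((azim + 90.0) / 180.0 * m).astype(int), 0, m - 1)
    radiance = np.where(inside[..., None], truth.pixels[i, j], 0.0)

    theta = np.where(inside, radius_to_theta(np.clip(r_norm, 0.0, 1.0)), 0.0)
    v = np.interp(theta, VIGNETTING_THETA_GRID, cal.vignetting_for(base_meta.f_number))
    gain0 = cal.iso_gain_for(base_meta.iso) * cal.aperture_gain_for(base_meta.f_number)
    k = cal.scale_vector()

    exposures = []
    for ev in ev_offsets:
        t = base_meta.exposure_time * 2.0 ** ev
        counts = radiance * (v[..., None] * t * gain0 / k) + cal.black_level
        counts = np.clip(counts, 0.0, cal.white_level)
        if quantize:
            counts = np.rint(counts)
        meta = ExposureMeta(
            exposure_time=t,
            iso=base_meta.iso,
            f_number=base_meta.f_number,
            ev_offset=float(ev),
        )
        exposures.append(
            FisheyeExposure(
                pixels=counts, meta=meta, center=center, radius_px=radius
            )
        )
    return exposures
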